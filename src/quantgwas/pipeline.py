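"""End-to-end orchestration: score -> five scans -> hit selection ->
quantile process -> Delta-R2 -> report; plus small genetics utilities
(APOE-4 allele counting, two-locus LD by EM, insulin unit conversion,
Bonferroni correction)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import quantreg, scan as scan_mod, scoring
from .simulate import GenotypeMatrix, read_cohort_tsv

logger = logging.getLogger(__name__)

#: pmol/l per mIU/l for insulin
INSULIN_PMOL_PER_MIU = 6.945


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def convert_insulin_units(value_miu_per_l: float) -> float:
    """Convert insulin from mIU/l to pmol/l (x 6.945); no rounding here."""
    if value_miu_per_l < 0:
        raise ValueError("insulin concentration cannot be negative")
    return value_miu_per_l * INSULIN_PMOL_PER_MIU


# ---------------------------------------------------------------------------
# APOE-4 allele counting from rs429358 / rs7412
# ---------------------------------------------------------------------------

def apoe4_count(g_rs429358: str | None, g_rs7412: str | None):
    """Number of APOE-e4 alleles from the two coding-SNP genotypes.

    Haplotypes (rs429358, rs7412): e2 = (T,T), e3 = (T,C), e4 = (C,C);
    the rare e1 = (C,T) is assumed absent, so the e4 count equals the
    number of C alleles at rs429358.  The double heterozygote (T/C, C/T)
    is phase-ambiguous between e2/e4 and e1/e3 and is resolved to e2/e4
    (count 1) with ``ambiguous=True``; combinations that would force an
    e1 haplotype are likewise flagged.  Missing input gives ``(None, False)``.
    """
    def _norm(g):
        if g is None or (isinstance(g, float) and np.isnan(g)):
            return None
        g = str(g).upper().replace("/", "")
        if sorted(g) not in (["C", "C"], ["C", "T"], ["T", "T"]):
            raise ValueError(f"invalid genotype {g!r}")
        return "".join(sorted(g))

    a, b = _norm(g_rs429358), _norm(g_rs7412)
    if a is None or b is None:
        return None, False
    n_c_429358 = a.count("C")
    n_c_7412 = b.count("C")
    count = n_c_429358
    # every 429358-C must pair with a 7412-C to be e4; shortfall implies e1
    ambiguous = (a == "CT" and b == "CT") or (n_c_7412 < n_c_429358)
    return count, ambiguous


# ---------------------------------------------------------------------------
# two-locus linkage disequilibrium via EM haplotype frequencies
# ---------------------------------------------------------------------------

def ld_two_locus(g1, g2, tol: float = 1e-10, max_iter: int = 1000):
    """D, D' and r^2 between two loci from unphased dosages.

    Haplotype frequencies are estimated by EM over the double-heterozygote
    phase ambiguity; D = p_AB - p_A p_B, D' = D / D_max, and
    r^2 = D^2 / (p_A p_a p_B p_b).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    if n == 0:
        raise ValueError("no complete genotype pairs")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise ValueError("monomorphic locus: LD undefined")

    pA = g1.mean() / 2.0
    pB = g2.mean() / 2.0
    # haplotypes: AB, Ab, aB, ab ("A"/"B" = effect alleles)
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    counts = {(int(a), int(b)): int(np.sum((g1 == a) & (g2 == b)))
              for a in (0, 1, 2) for b in (0, 1, 2)}
    # known haplotype contributions of each unambiguous genotype pair
    base = np.zeros(4)
    for (a, b), c in counts.items():
        if c == 0 or (a == 1 and b == 1):
            continue
        base += c * np.array(_phase_known(a, b))
    n_dh = counts[(1, 1)]
    for _ in range(max_iter):
        # split double heterozygotes between AB/ab and Ab/aB phases
        w_cis = p[0] * p[3]
        w_trans = p[1] * p[2]
        tot = w_cis + w_trans
        f_cis = 0.5 if tot == 0 else w_cis / tot
        hap = base + n_dh * np.array([f_cis, 1 - f_cis, 1 - f_cis, f_cis])
        p_new = hap / (2.0 * n)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    else:
        raise RuntimeError("EM for haplotype frequencies did not converge")

    pA = p[0] + p[1]
    pB = p[0] + p[2]
    D = p[0] - pA * pB
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom == 0 else D**2 / denom
    return float(D), float(d_prime), float(r2)


def _phase_known(a: int, b: int):
    """Haplotype counts (AB, Ab, aB, ab) for a phase-unambiguous genotype."""
    if a == 1 and b == 1:
        raise ValueError("double heterozygote is phase ambiguous")
    nAB = nAb = naB = nab = 0
    # locus1 contributes a A-alleles and (2-a) a-alleles; when either locus
    # is homozygous the pairing is forced
    if a == 2:
        nAB, nAb = b, 2 - b
    elif a == 0:
        naB, nab = b, 2 - b
    elif b == 2:          # a == 1
        nAB, naB = 1, 1
    else:                 # a == 1, b == 0
        nAb, nab = 1, 1
    return nAB, nAb, naB, nab


# ---------------------------------------------------------------------------
# run configuration and the pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    pheno_path: str
    geno_path: str
    out_dir: str
    reference_path: str | None = None    # None -> score against the sample itself
    outcomes: tuple = ("P15", "P25", "P50", "P75", "P85")
    genomewide: float = scan_mod.GENOMEWIDE_P
    suggestive: float = scan_mod.SUGGESTIVE_P
    reporting_alpha: float = 0.05
    tau_grid: tuple = tuple(quantreg.DEFAULT_TAU_GRID.tolist())
    n_pcs: int = 32
    bin_width: float = 1.0
    min_stratum: int = 30
    include_age2: bool = True
    include_survey: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.genomewide < self.suggestive):
            raise ValueError("need 0 < genome-wide threshold < suggestive")

    def validate_paths(self) -> None:
        for p in (self.pheno_path, self.geno_path, self.reference_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


@dataclass
class RunReport:
    config_fingerprint: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    n_hits: int = 0
    hit_snps: list = field(default_factory=list)
    bonferroni_level: float = np.nan
    significant_hs: list = field(default_factory=list)
    significant_linear: list = field(default_factory=list)
    log: list = field(default_factory=list)

    def note(self, msg: str) -> None:
        self.log.append(f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] {msg}")
        logger.info(msg)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and write all result tables.

    Stages: reduce to first valid observation per child, fit the empirical
    reference and score percentile ranks, compute genotype PCs, run the
    five logistic scans, select SNPs reaching suggestive significance in
    any scan, fit the quantile-coefficient process with heteroscedasticity
    and linear tests for each hit (Bonferroni level alpha / number of
    profiled SNPs, covering the union of both test families), and compute
    per-outcome Delta-R2 profiles.  Deterministic given the config.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_fingerprint=config.fingerprint(), seed=config.seed)

    cohort = read_cohort_tsv(config.pheno_path)
    report.stage_counts["input_rows"] = len(cohort)
    if cohort["id"].duplicated().any():
        cohort = scoring.select_first_observation(cohort)
    report.stage_counts["analysed_children"] = len(cohort)
    report.note(f"analytical sample: {len(cohort)} children")

    geno = GenotypeMatrix.from_tsv(config.geno_path) \
        if not str(config.geno_path).endswith(".vcf") \
        else GenotypeMatrix.from_vcf(config.geno_path)
    order = pd.Index(geno.sample_ids).get_indexer(cohort["id"])
    if np.any(order < 0):
        raise ValueError("phenotype ids missing from the genotype matrix")
    geno.dosages = geno.dosages[order]
    geno.sample_ids = geno.sample_ids[order]
    report.stage_counts["n_snps"] = geno.n_snps

    reference = (read_cohort_tsv(config.reference_path)
                 if config.reference_path else cohort)
    model = scoring.fit_reference(reference, config.bin_width, config.min_stratum)
    scored = scoring.score_table(model, cohort)
    model.to_json(out / "reference_model.json")
    _write(scored, out / "scored_phenotypes.tsv")
    report.note("scoring complete")

    k = min(config.n_pcs, max(1, len(cohort) // 50), geno.n_snps - 1)
    if k != config.n_pcs:
        report.note(f"PC count reduced from {config.n_pcs} to {k} for cohort size")
    pcs, explained = scan_mod.compute_pcs(geno, k)
    X = scan_mod.build_covariate_design(scored, pcs,
                                        include_age2=config.include_age2,
                                        include_survey=config.include_survey)

    all_scans = []
    for outcome in config.outcomes:
        y = scan_mod.define_cases(scored, outcome)
        recs = scan_mod.gwa_scan(geno, y, X, outcome_label=outcome,
                                 genomewide=config.genomewide,
                                 suggestive=config.suggestive)
        _write(recs, out / f"scan_{outcome}.tsv")
        _write(scan_mod.manhattan_table(recs), out / f"manhattan_{outcome}.tsv")
        all_scans.append(recs)
        report.note(f"scan {outcome}: {int((recs['tier'] != 'none').sum())} hits")
    scans = pd.concat(all_scans, ignore_index=True)
    report.stage_counts["scan_rows"] = len(scans)

    hits = scans[scans["tier"].isin(["genome-wide", "suggestive"])]
    hit_snps = sorted(hits["snp_id"].unique().tolist())
    report.n_hits = len(hit_snps)
    report.hit_snps = hit_snps

    y_log = scored["log_insulin"].to_numpy(dtype=float)
    tau_grid = np.asarray(config.tau_grid)
    if not hit_snps:
        report.note("empty hit list: quantile-process stage skipped, 0 profiles")
        report.stage_counts["profile_rows"] = 0
    else:
        m_tests = len(hit_snps)
        level = bonferroni_threshold(config.reporting_alpha, m_tests)
        report.bonferroni_level = level
        prof_rows, test_rows = [], []
        for snp in hit_snps:
            eaf, _, g = scan_mod.effect_allele_freq(geno.column(snp))
            ok = ~np.isnan(g)
            Xg = np.column_stack([X[ok], g[ok]])
            prof = quantreg.quantile_process(y_log[ok], Xg, tau_grid,
                                             snp_column=-1, snp_id=snp)
            for i, tau in enumerate(tau_grid):
                prof_rows.append({"snp_id": snp, "tau": tau,
                                  "beta": prof.beta_path[i],
                                  "se": prof.se_path[i],
                                  "ci_low": prof.ci_low[i],
                                  "ci_high": prof.ci_high[i]})
            test_rows.append({"snp_id": snp, "eaf": eaf,
                              "hs_chi2": prof.hs_chi2, "hs_df": prof.hs_df,
                              "hs_p": prof.hs_p,
                              "hs_significant": prof.hs_p < level,
                              "linear_beta": prof.linear_beta,
                              "linear_se": prof.linear_se,
                              "linear_p": prof.linear_p,
                              "linear_significant": prof.linear_p < level})
        profiles = pd.DataFrame(prof_rows)
        tests = pd.DataFrame(test_rows)
        _write(profiles, out / "quantile_profiles.tsv")
        _write(tests, out / "quantile_tests.tsv")
        report.stage_counts["profile_rows"] = len(profiles)
        report.significant_hs = tests.loc[tests["hs_significant"], "snp_id"].tolist()
        report.significant_linear = tests.loc[tests["linear_significant"],
                                              "snp_id"].tolist()
        report.note(f"profiled {len(hit_snps)} SNPs at Bonferroni level {level:g}")

        # Delta-R2 per outcome hit set, against the non-genetic base model
        sets = {}
        for outcome in config.outcomes:
            snps = sorted(hits.loc[hits["outcome"] == outcome, "snp_id"].unique())
            if snps:
                sets[outcome] = [geno.column_index(s) for s in snps]
        if sets:
            G_minor = np.column_stack([
                scan_mod.effect_allele_freq(geno.dosages[:, j])[2]
                for j in range(geno.n_snps)]) if geno.n_snps else geno.dosages
            # Delta-R2 needs complete dosages; mean-impute the rare missing
            col_mu = np.nanmean(G_minor, axis=0)
            nan_at = np.isnan(G_minor)
            G_minor[nan_at] = np.take(col_mu, np.nonzero(nan_at)[1])
            deltas = quantreg.delta_r2_profile(y_log, X, G_minor, sets, tau_grid)
            drows = [{"set": lbl, "tau": tau, "delta_r2_adj": d[i]}
                     for lbl, d in deltas.items()
                     for i, tau in enumerate(tau_grid)]
            _write(pd.DataFrame(drows), out / "delta_r2.tsv")
            report.note(f"Delta-R2 profiles for {len(sets)} outcome sets")

    report.to_json(out / "report.json")
    return report
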