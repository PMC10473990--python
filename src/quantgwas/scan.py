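"""Tail-dichotomised logistic genome-wide association scans.

Five outcomes are derived from the age/sex-specific percentile rank of
fasting insulin: P15 and P25 compare children at or below the threshold
rank against everyone above it ("low for age and sex"), while P50, P75
and P85 compare children at or above the threshold against everyone
below.  Each SNP enters an additive logistic model (effect-allele dosage
0/1/2, minor-allele orientation) alongside age, age^2, sex, BMI, survey
and country indicators and genotype-derived principal components.
Associations are tiered at genome-wide (5e-8) and suggestive (1e-5)
significance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm, chi2

logger = logging.getLogger(__name__)

GENOMEWIDE_P = 5e-8
SUGGESTIVE_P = 1e-5

#: outcome label -> (threshold rank in percent, tail: "low" or "high")
OUTCOME_DEFS = {
    "P15": (15.0, "low"),
    "P25": (25.0, "low"),
    "P50": (50.0, "high"),
    "P75": (75.0, "high"),
    "P85": (85.0, "high"),
}


def define_cases(scores: pd.DataFrame, outcome_label: str) -> np.ndarray:
    """Binary case vector for one percentile-rank outcome.

    P15/P25: case iff rank <= threshold; P50/P75/P85: case iff
    rank >= threshold.  The complement is the control group.
    """
    if outcome_label not in OUTCOME_DEFS:
        raise ValueError(f"unknown outcome {outcome_label!r}")
    thresh, tail = OUTCOME_DEFS[outcome_label]
    ranks = scores["percentile_rank"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ranks)):
        raise ValueError("percentile ranks missing for some individuals")
    y = (ranks <= thresh) if tail == "low" else (ranks >= thresh)
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == len(y):
        raise ValueError(
            f"{outcome_label}: degenerate outcome ({n_cases} cases of {len(y)})")
    return y.astype(float)


# ---------------------------------------------------------------------------
# principal components of the dosage matrix
# ---------------------------------------------------------------------------

def _ld_prune(Z: np.ndarray, r2_threshold: float) -> np.ndarray:
    """Greedy pruning: keep a SNP only if its r2 with every kept SNP is
    below the threshold.  Returns kept column indices."""
    n, m = Z.shape
    kept: list[int] = []
    for j in range(m):
        if kept:
            r = (Z[:, kept].T @ Z[:, j]) / n
            if np.max(r**2) >= r2_threshold:
                continue
        kept.append(j)
    return np.asarray(kept, dtype=int)


def compute_pcs(genotypes, k: int, prune_r2: float | None = None):
    """Top-k principal components of the standardised dosage matrix.

    Missing dosages are mean-imputed per SNP (only inside the PCA);
    constant SNPs are excluded.  ``prune_r2`` optionally LD-prunes the
    matrix first (greedy, keeping SNPs whose pairwise r2 with already-kept
    SNPs stays below the threshold).  Returns ``(scores,
    explained_ratio)`` where the score columns are orthonormal and ordered
    by explained variance.
    """
    G = np.asarray(getattr(genotypes, "dosages", genotypes), dtype=float).copy()
    n, m = G.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n, n_snps)={min(n, m)}")
    mu = np.nanmean(G, axis=0)
    nanmask = np.isnan(G)
    G[nanmask] = np.take(mu, np.nonzero(nanmask)[1])
    sd = G.std(axis=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all SNPs are constant; PCA undefined")
    if not np.all(keep):
        logger.info("excluding %d constant SNPs from PCA", int((~keep).sum()))
    Z = (G[:, keep] - mu[keep]) / sd[keep]
    Z -= Z.mean(axis=0)
    if prune_r2 is not None:
        cols = _ld_prune(Z / np.maximum(Z.std(axis=0), 1e-12), prune_r2)
        if k >= len(cols):
            raise ValueError("k exceeds the number of SNPs left after pruning")
        logger.info("LD pruning kept %d of %d SNPs", len(cols), Z.shape[1])
        Z = Z[:, cols]
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    explained = S**2 / np.sum(S**2)
    return U[:, :k], explained[:k]


# ---------------------------------------------------------------------------
# covariate design
# ---------------------------------------------------------------------------

def build_covariate_design(cohort: pd.DataFrame, pcs=None,
                           include_age2: bool = True,
                           include_survey: bool = True,
                           bmi_col: str = "bmi") -> np.ndarray:
    """Design matrix: intercept, age, (age^2), sex, BMI, survey and country
    indicators (reference categories dropped), PC columns.

    ``bmi_col`` selects the adiposity covariate (raw ``"bmi"`` by default;
    pass a BMI z-score column to use the standardised alternative).
    Raises if the assembled matrix is rank deficient.
    """
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    age = cohort["age_years"].to_numpy(dtype=float)
    cols.append(age); names.append("age")
    if include_age2:
        cols.append(age**2); names.append("age2")
    cols.append(cohort["sex"].to_numpy(dtype=float)); names.append("sex")
    cols.append(cohort[bmi_col].to_numpy(dtype=float)); names.append(bmi_col)
    for cat_col, use in (("survey", include_survey), ("country", True)):
        if use and cat_col in cohort.columns:
            dummies = pd.get_dummies(cohort[cat_col], prefix=cat_col,
                                     drop_first=True, dtype=float)
            for c in dummies.columns:
                v = dummies[c].to_numpy()
                if v.std() > 0:
                    cols.append(v); names.append(c)
    X = np.column_stack(cols)
    if pcs is not None and np.size(pcs):
        X = np.column_stack([X, np.asarray(pcs, dtype=float)])
        names += [f"PC{i+1}" for i in range(np.asarray(pcs).shape[1])]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    return X


# ---------------------------------------------------------------------------
# logistic regression by IRLS
# ---------------------------------------------------------------------------

def logistic_fit(y, X, max_iter: int = 50, start=None):
    """Maximum-likelihood logistic regression via IRLS.

    Converges when max |score| < 1e-8 or the relative deviance change is
    < 1e-10, within ``max_iter`` iterations.  Covariance is the inverse
    observed information.  Complete or quasi-complete separation and
    non-convergence are reported through ``converged=False``; estimates
    are retained.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all responses identical")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    dev_old = np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < 1e-8:
            converged = True
            break
        XtWX = (X * np.maximum(w, 1e-10)[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        dev = -2.0 * np.sum(y * np.log(np.maximum(mu, 1e-300))
                            + (1 - y) * np.log(np.maximum(1 - mu, 1e-300)))
        if np.isfinite(dev_old) and abs(dev_old - dev) < 1e-10 * (abs(dev) + 1e-10):
            converged = True
            break
        dev_old = dev
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    # quasi-complete separation: fitted probabilities collapse to 0/1
    if converged and np.min(np.maximum(w, 0)) < 1e-12 and np.max(np.abs(beta)) > 15:
        converged = False
    XtWX = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return beta, cov, converged


def wald_p(beta: float, se: float) -> float:
    """Two-sided Wald p value from z = beta/SE against the standard normal."""
    if se <= 0 or not np.isfinite(se):
        return np.nan
    return float(max(2.0 * norm.sf(abs(beta) / se), np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# effect-allele orientation
# ---------------------------------------------------------------------------

def effect_allele_freq(dosages) -> tuple:
    """EAF with minor-allele orientation.

    Returns ``(eaf, flipped, recoded)``: if the raw allele frequency
    exceeds 0.5 the dosages are recoded 2-g so the effect allele is the
    minor allele.  Missing dosages are excluded from the frequency.
    """
    g = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(g)
    if not np.any(ok):
        raise ValueError("all dosages missing")
    eaf = float(np.sum(g[ok]) / (2.0 * ok.sum()))
    if eaf > 0.5:
        return 1.0 - eaf, True, np.where(ok, 2.0 - g, np.nan)
    return eaf, False, g


def classify_hits(records: pd.DataFrame, genomewide: float = GENOMEWIDE_P,
                  suggestive: float = SUGGESTIVE_P) -> pd.DataFrame:
    """Tier each association: genome-wide (p < 5e-8), suggestive (p < 1e-5)."""
    p = records["p"].to_numpy(dtype=float)
    tier = np.where(p < genomewide, "genome-wide",
                    np.where(p < suggestive, "suggestive", "none"))
    tier[~np.isfinite(p)] = "none"
    out = records.copy()
    out["tier"] = tier
    return out


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def gwa_scan(genotypes, outcome, covariates, outcome_label: str = "",
             genomewide: float = GENOMEWIDE_P,
             suggestive: float = SUGGESTIVE_P,
             sex: np.ndarray | None = None) -> pd.DataFrame:
    """One logistic association record per SNP for one outcome.

    Individuals with a missing dosage at a SNP are dropped for that SNP
    only.  Monomorphic SNPs yield an NA record with ``converged=False``.
    Passing ``sex`` (0/1 vector) adds an a-posteriori genotype-by-sex
    interaction term and reports its Wald p as ``sex_int_p`` (off by
    default; the main dosage effect is then sex-adjusted as before).
    """
    y = np.asarray(outcome, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    n = len(y)
    if genotypes.n_individuals != n or X.shape[0] != n:
        raise ValueError("genotypes, outcome and covariates must be aligned")

    # warm start from the covariates-only fit
    beta0, _, _ = logistic_fit(y, X)
    rows = []
    for j in range(genotypes.n_snps):
        g_raw = genotypes.dosages[:, j]
        rec = {
            "snp_id": genotypes.snp_ids[j],
            "chrom": genotypes.chrom[j], "pos": genotypes.pos[j],
            "ref_allele": genotypes.ref_allele[j],
            "eff_allele": genotypes.eff_allele[j],
            "outcome": outcome_label,
        }
        try:
            eaf, flipped, g = effect_allele_freq(g_raw)
        except ValueError:
            rows.append({**rec, "eaf": np.nan, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "or": np.nan, "n_cases": 0,
                         "n_controls": 0, "flipped": False, "converged": False})
            continue
        ok = ~np.isnan(g)
        gj, yj, Xj = g[ok], y[ok], X[ok]
        if np.ptp(gj) == 0:  # monomorphic
            rows.append({**rec, "eaf": eaf, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "or": np.nan,
                         "n_cases": int(yj.sum()),
                         "n_controls": int(len(yj) - yj.sum()),
                         "flipped": flipped, "converged": False})
            continue
        if sex is not None:
            sj = np.asarray(sex, dtype=float)[ok]
            Xfull = np.column_stack([Xj, gj, gj * sj])
            start = np.append(beta0, [0.0, 0.0])
            b, cov, conv = logistic_fit(yj, Xfull, start=start)
            g_idx = -2
            se_int = (float(np.sqrt(cov[-1, -1]))
                      if np.isfinite(cov[-1, -1]) else np.nan)
            extra = {"sex_int_beta": float(b[-1]),
                     "sex_int_p": wald_p(b[-1], se_int)}
        else:
            Xfull = np.column_stack([Xj, gj])
            start = np.append(beta0, 0.0)
            b, cov, conv = logistic_fit(yj, Xfull, start=start)
            g_idx = -1
            extra = {}
        se = (float(np.sqrt(cov[g_idx, g_idx]))
              if np.isfinite(cov[g_idx, g_idx]) else np.nan)
        rows.append({**rec, "eaf": eaf, "beta": float(b[g_idx]), "se": se,
                     "p": wald_p(b[g_idx], se), "or": float(np.exp(b[g_idx])),
                     "n_cases": int(yj.sum()),
                     "n_controls": int(len(yj) - yj.sum()),
                     "flipped": flipped, "converged": conv, **extra})
    df = pd.DataFrame(rows)
    return classify_hits(df, genomewide, suggestive)


def genomic_control_lambda(p_values) -> float:
    """Median association chi-square over its null median (calibration check)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chisq = chi2.isf(p, df=1)
    return float(np.median(chisq) / chi2.isf(0.5, df=1))


def manhattan_table(records: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready export: chrom, pos, -log10 p."""
    out = records[["snp_id", "chrom", "pos"]].copy()
    out["neglog10p"] = -np.log10(records["p"].to_numpy(dtype=float))
    return out
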