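"""Age- and sex-specific percentile ranks and z scores of fasting insulin.

Insulin rises steeply through childhood, so raw values are not comparable
across ages.  Children are therefore scored against a reference sample
within (sex, age-bin) strata: the percentile rank is the interpolated
mid-ECDF position of the child's insulin in its stratum (in percent), and
z = Phi^{-1}(rank/100).  Ranks are clamped away from 0 and 100 so z is
always finite.  The reference sample is user-suppliable (the published
analysis scored against an external normal-weight reference, which is why
a cohort's mean rank can exceed 50); it defaults to the analysis sample
itself.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass
class _Stratum:
    sex: int
    age_lo: float
    age_hi: float
    values: np.ndarray  # sorted, strictly positive

    @property
    def count(self) -> int:
        return len(self.values)

    @property
    def center(self) -> float:
        return 0.5 * (self.age_lo + self.age_hi)


@dataclass
class ReferenceModel:
    """Empirical sex x age-bin reference for percentile-rank scoring."""

    bin_width: float
    min_stratum: int
    strata: dict = field(default_factory=dict)  # sex -> list[_Stratum], by age

    def strata_for(self, sex: int) -> list:
        if sex not in self.strata:
            raise ValueError(f"reference has no stratum for sex={sex}")
        return self.strata[sex]

    def to_json(self, path) -> None:
        d = {
            "bin_width": self.bin_width,
            "min_stratum": self.min_stratum,
            "strata": {
                str(sex): [
                    {"age_lo": s.age_lo, "age_hi": s.age_hi,
                     "values": s.values.tolist()}
                    for s in lst
                ]
                for sex, lst in self.strata.items()
            },
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        d = json.loads(Path(path).read_text())
        model = cls(bin_width=d["bin_width"], min_stratum=d["min_stratum"])
        for sex, lst in d["strata"].items():
            model.strata[int(sex)] = [
                _Stratum(int(sex), s["age_lo"], s["age_hi"],
                         np.asarray(s["values"], dtype=float))
                for s in lst
            ]
        return model


@dataclass
class ScoredValue:
    percentile_rank: float   # percent, in (0, 100)
    z: float                 # Phi^{-1}(rank/100)
    out_of_range: bool = False


def fit_reference(reference: pd.DataFrame, bin_width: float = 1.0,
                  min_stratum: int = 30,
                  value_col: str = "insulin_pmol_l") -> ReferenceModel:
    """Build the empirical reference from a cohort table.

    Strata are (sex, age-bin) with bins of ``bin_width`` years spanning the
    reference age range; a stratum below ``min_stratum`` is merged with the
    nearest adjacent age bin of the same sex until all strata are large
    enough.
    """
    if reference.empty:
        raise ValueError("reference table is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = reference[value_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError(f"{value_col} must be finite and > 0")
    sexes = sorted(reference["sex"].unique().tolist())
    for sex in (0, 1):
        if sex not in sexes:
            raise ValueError(f"sex {sex} entirely absent from the reference")

    model = ReferenceModel(bin_width=bin_width, min_stratum=min_stratum)
    for sex in sexes:
        sub = reference[reference["sex"] == sex]
        ages = sub["age_years"].to_numpy(dtype=float)
        v = sub[value_col].to_numpy(dtype=float)
        lo = np.floor(ages.min() / bin_width) * bin_width
        n_bins = max(1, int(np.ceil((ages.max() - lo) / bin_width + 1e-9)))
        edges = lo + bin_width * np.arange(n_bins + 1)
        idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, n_bins - 1)
        strata = [
            _Stratum(sex, float(edges[k]), float(edges[k + 1]),
                     np.sort(v[idx == k]))
            for k in range(n_bins)
        ]
        strata = [s for s in strata if s.count > 0]
        strata = _merge_small(strata, min_stratum)
        if len(strata) == 1 and strata[0].count < min_stratum:
            raise ValueError(
                f"all strata for sex={sex} below min_stratum={min_stratum}")
        model.strata[sex] = strata
    return model


def _merge_small(strata: list, min_stratum: int) -> list:
    """Merge undersized strata into an adjacent age bin of the same sex."""
    strata = list(strata)
    while len(strata) > 1:
        sizes = [s.count for s in strata]
        k = int(np.argmin(sizes))
        if sizes[k] >= min_stratum:
            break
        if k == 0:
            j = 1
        elif k == len(strata) - 1:
            j = k - 1
        else:
            j = k - 1 if strata[k - 1].count <= strata[k + 1].count else k + 1
        a, b = (strata[j], strata[k]) if j < k else (strata[k], strata[j])
        merged = _Stratum(a.sex, a.age_lo, b.age_hi,
                          np.sort(np.concatenate([a.values, b.values])))
        lo_i = min(j, k)
        strata[lo_i:lo_i + 2] = [merged]
    return strata


def _find_stratum(model: ReferenceModel, sex: int, age: float):
    strata = model.strata_for(int(sex))
    for s in strata:
        if s.age_lo <= age < s.age_hi:
            return s, False
    # boundary: exact top edge belongs to the last bin
    if age == strata[-1].age_hi:
        return strata[-1], False
    # uncovered age: nearest bin by centre, flagged
    dists = [min(abs(age - s.age_lo), abs(age - s.age_hi)) for s in strata]
    return strata[int(np.argmin(dists))], True


def _mid_ecdf_rank(values: np.ndarray, x: float) -> float:
    """Interpolated mid-ECDF position of x among sorted values, in [0,1]."""
    n = len(values)
    lo = np.searchsorted(values, x, side="left")
    hi = np.searchsorted(values, x, side="right")
    if hi > lo:                       # exact tie(s): mid-count
        f = (lo + 0.5 * (hi - lo)) / n
    elif lo == 0 or lo == n:          # outside the observed range
        f = 0.0 if lo == 0 else 1.0
    else:                             # between two order statistics
        f_lo = (lo - 0.5) / n
        f_hi = (lo + 0.5) / n
        w = (x - values[lo - 1]) / (values[lo] - values[lo - 1])
        f = f_lo + w * (f_hi - f_lo)
    return float(np.clip(f, 0.5 / n, (n - 0.5) / n))


def score_value(model: ReferenceModel, sex: int, age: float,
                insulin: float) -> ScoredValue:
    """Percentile rank (percent) and z score of one insulin value."""
    if not np.isfinite(insulin) or insulin <= 0:
        raise ValueError("insulin must be finite and > 0")
    stratum, flagged = _find_stratum(model, sex, age)
    rank = 100.0 * _mid_ecdf_rank(stratum.values, insulin)
    return ScoredValue(percentile_rank=rank, z=float(norm.ppf(rank / 100.0)),
                       out_of_range=flagged)


def _mid_ecdf_rank_vec(values: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Vectorised interpolated mid-ECDF over one stratum."""
    n = len(values)
    lo = np.searchsorted(values, xs, side="left")
    hi = np.searchsorted(values, xs, side="right")
    f = np.empty(len(xs))
    tie = hi > lo
    f[tie] = (lo[tie] + 0.5 * (hi[tie] - lo[tie])) / n
    below, above = ~tie & (lo == 0), ~tie & (lo == n)
    f[below], f[above] = 0.0, 1.0
    mid = ~(tie | below | above)
    lm = lo[mid]
    w = (xs[mid] - values[lm - 1]) / (values[lm] - values[lm - 1])
    f[mid] = (lm - 0.5 + w) / n
    return np.clip(f, 0.5 / n, (n - 0.5) / n)


def score_table(model: ReferenceModel, cohort: pd.DataFrame,
                value_col: str = "insulin_pmol_l") -> pd.DataFrame:
    """Score every row of a cohort table.

    Returns the cohort with added columns ``percentile_rank``, ``z`` and
    ``log_insulin`` (natural log of insulin in pmol/l).
    """
    vals = cohort[value_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError(f"{value_col} must be finite and > 0")
    ages = cohort["age_years"].to_numpy(dtype=float)
    sexes = cohort["sex"].to_numpy(dtype=int)
    ranks = np.empty(len(cohort))
    flags = np.zeros(len(cohort), dtype=bool)
    for sex in np.unique(sexes):
        strata = model.strata_for(int(sex))
        sel = sexes == sex
        # assign each row to its covering stratum, nearest bin if uncovered
        edges_lo = np.array([s.age_lo for s in strata])
        edges_hi = np.array([s.age_hi for s in strata])
        idx = np.searchsorted(edges_lo, ages[sel], side="right") - 1
        idx = np.clip(idx, 0, len(strata) - 1)
        covered = (ages[sel] >= edges_lo[idx]) & (ages[sel] <= edges_hi[idx])
        flags[sel] = ~covered
        rows = np.where(sel)[0]
        for k, s in enumerate(strata):
            in_k = rows[idx == k]
            if len(in_k):
                ranks[in_k] = 100.0 * _mid_ecdf_rank_vec(s.values, vals[in_k])
    # uncovered ages (gaps or out of range): nearest-bin scalar rule
    for i in np.where(flags)[0]:
        s = score_value(model, int(sexes[i]), float(ages[i]), float(vals[i]))
        ranks[i] = s.percentile_rank
    zs = norm.ppf(ranks / 100.0)
    out = cohort.copy()
    out["percentile_rank"] = ranks
    out["z"] = zs
    out["log_insulin"] = np.log(out[value_col].to_numpy(dtype=float))
    out["rank_out_of_range"] = flags
    return out


#: validity flags: column name -> value a valid record must have
VALIDITY_FLAGS = {"fasted_8h": True, "diabetes": False, "glucose_med": False}


def select_first_observation(long_table: pd.DataFrame) -> pd.DataFrame:
    """Reduce a longitudinal table to one valid record per child.

    Keeps, per id, the valid record at the youngest age (the child's first
    valid insulin measurement).  A record is valid when every flag column
    present in the table matches ``VALIDITY_FLAGS`` (fasted at least 8 h,
    no diabetes diagnosis, no glucose-lowering medication).  Children with
    no valid record are excluded and logged.
    """
    df = long_table
    valid = np.ones(len(df), dtype=bool)
    for col, required in VALIDITY_FLAGS.items():
        if col in df.columns:
            valid &= df[col].astype(bool).to_numpy() == required
    df = df[valid]
    dropped = set(long_table["id"]) - set(df["id"])
    if dropped:
        logger.info("excluding %d children with no valid record", len(dropped))
    out = (df.sort_values(["id", "age_years"], kind="mergesort")
             .groupby("id", as_index=False, sort=True).first())
    return out.reset_index(drop=True)
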