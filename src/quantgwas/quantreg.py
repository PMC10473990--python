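"""Quantile-regression process machinery.

Check-loss estimation over a grid of quantile levels, sparsity-based
standard errors, the joint covariance of a coefficient across the grid,
a Wald test for heteroscedasticity (i.e. for a quantile-varying effect),
Koenker–Machado goodness of fit R1 and Delta-R1 profiles, and the
companion ordinary-least-squares effect size.

The estimator minimises the asymmetric check loss

    rho_tau(u) = u * (tau - 1{u < 0})

which is solved exactly as a linear program.  We solve the *dual* LP
(max y'a subject to X'a = (1-tau) X'1, 0 <= a <= 1), which has only p
equality constraints and is much faster than the primal at GWAS sample
sizes; the primal basic solution is recovered from the interior dual
variables (complementary slackness: an interior a_i forces a zero
residual).  If the recovery is degenerate we fall back to the primal LP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.stats import chi2, norm, t as t_dist

logger = logging.getLogger(__name__)

#: default grid of quantile levels: 0.05, 0.10, ..., 0.95 (19 levels)
DEFAULT_TAU_GRID: np.ndarray = np.round(np.arange(1, 20) * 0.05, 2)

_SPARSITY_FLOOR = 1e-6
_GAP_TOL = 1e-7  # relative duality-gap tolerance for dual-basis recovery


# ---------------------------------------------------------------------------
# check loss and the LP fit
# ---------------------------------------------------------------------------

def check_loss(u, tau: float):
    """Asymmetric check loss rho_tau(u) = u * (tau - 1{u<0}), elementwise."""
    _validate_tau(tau)
    u = np.asarray(u, dtype=float)
    return u * (tau - (u < 0))


def _validate_tau(tau: float) -> None:
    if not 0.0 < tau < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {tau}")


@dataclass
class QuantileFit:
    """Result of a single check-loss fit at level ``tau``."""

    tau: float
    coefficients: np.ndarray
    objective: float
    residuals: np.ndarray
    sparsity: float | None = None
    sparsity_clamped: bool = False


def _type1_quantile(y: np.ndarray, tau: float) -> float:
    """Lower-endpoint (type-1) empirical quantile: y_(ceil(n*tau))."""
    ys = np.sort(y)
    k = int(np.ceil(len(ys) * tau))
    return float(ys[max(k, 1) - 1])


def _fit_primal_lp(y: np.ndarray, X: np.ndarray, tau: float) -> np.ndarray:
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A = sp.hstack(
        [sp.csc_matrix(X), sp.eye(n, format="csc"), -sp.eye(n, format="csc")],
        format="csc",
    )
    res = linprog(c, A_eq=A, b_eq=y, bounds=[(None, None)] * p + [(0, None)] * (2 * n),
                  method="highs")
    if not res.success:  # pragma: no cover - valid inputs are always feasible
        raise RuntimeError(f"primal quantile LP failed: {res.message}")
    return res.x[:p]


def fit_quantile(y, X, tau: float) -> QuantileFit:
    """Minimise sum_i rho_tau(y_i - x_i'beta) exactly (linear programming).

    Ties are broken by returning an LP basic (vertex) solution; for an
    intercept-only design this is the lower endpoint of the minimising
    interval, i.e. the type-1 empirical quantile.
    """
    _validate_tau(tau)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have incompatible shapes")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    if p == 1 and np.ptp(X[:, 0]) == 0.0:
        # intercept-only: closed form, lower endpoint of the minimising interval
        beta = np.array([_type1_quantile(y, tau) / X[0, 0]])
    else:
        beta = _fit_dual_lp(y, X, tau)
        if beta is None:
            beta = _fit_primal_lp(y, X, tau)

    resid = y - X @ beta
    obj = float(np.sum(check_loss(resid, tau)))
    return QuantileFit(tau=tau, coefficients=beta, objective=obj, residuals=resid)


def _fit_dual_lp(y: np.ndarray, X: np.ndarray, tau: float) -> np.ndarray | None:
    """Solve the dual LP and recover the primal vertex; None if degenerate."""
    n, p = X.shape
    res = linprog(-y, A_eq=X.T, b_eq=(1.0 - tau) * X.sum(axis=0),
                  bounds=[(0.0, 1.0)] * n, method="highs")
    if not res.success:
        return None
    a = res.x
    interior = np.where((a > 1e-7) & (a < 1.0 - 1e-7))[0]
    if len(interior) < p:
        return None
    beta, *_ = np.linalg.lstsq(X[interior], y[interior], rcond=None)
    # verify optimality through the duality gap
    dual_obj = -res.fun - (1.0 - tau) * y.sum()
    primal_obj = float(np.sum(check_loss(y - X @ beta, tau)))
    if abs(primal_obj - dual_obj) > _GAP_TOL * (1.0 + abs(dual_obj)):
        return None
    return beta


# ---------------------------------------------------------------------------
# sparsity (reciprocal error density) estimation
# ---------------------------------------------------------------------------

def hall_sheather_bandwidth(tau: float, n: int, alpha: float = 0.05) -> float:
    """Hall–Sheather bandwidth for the Siddiqui sparsity difference quotient."""
    z = norm.ppf(1.0 - alpha / 2.0)
    q = norm.ppf(tau)
    num = 1.5 * norm.pdf(q) ** 2
    den = 2.0 * q**2 + 1.0
    return n ** (-1.0 / 3.0) * z ** (2.0 / 3.0) * (num / den) ** (1.0 / 3.0)


def sparsity_estimate(fit: QuantileFit, n: int | None = None,
                      alpha: float = 0.05) -> float:
    """Siddiqui estimate of the sparsity s(tau) = 1/f(F^{-1}(tau)).

    The difference quotient [Q(tau+h) - Q(tau-h)] / (2h) is evaluated on the
    empirical quantile function of the fit residuals, with the Hall–Sheather
    bandwidth h clamped so that 0 < tau-h < tau+h < 1.  The basic
    residuals (exact zeros of the LP fit) are excluded from the quantile
    function first.  The estimate is floored at a small positive value
    (with a warning) so that standard errors stay finite.
    """
    tau = fit.tau
    resid = fit.residuals
    # the ~p basic residuals are exactly zero by construction; excluding
    # them from the empirical quantile function (as the classical
    # implementations do) removes a finite-sample downward bias in s
    nonzero = resid[np.abs(resid) > 1e-9]
    if len(nonzero) >= 3:
        resid = nonzero
    if n is None:
        n = len(resid)
    h = hall_sheather_bandwidth(tau, n, alpha)
    eps = 0.5 / n
    h_eff = min(h, tau - eps, 1.0 - tau - eps)
    if h_eff <= 0.0:
        raise ValueError(
            f"sample too small for a sparsity bandwidth at tau={tau} (n={n})")
    if h_eff < h:
        fit.sparsity_clamped = True
    q_lo, q_hi = np.quantile(resid, [tau - h_eff, tau + h_eff])
    s = (q_hi - q_lo) / (2.0 * h_eff)
    if s < _SPARSITY_FLOOR:
        warnings.warn(
            f"sparsity estimate {s:.3g} at tau={tau} floored at {_SPARSITY_FLOOR}",
            RuntimeWarning, stacklevel=2)
        s = _SPARSITY_FLOOR
    fit.sparsity = float(s)
    return float(s)


# ---------------------------------------------------------------------------
# the coefficient process over the tau grid
# ---------------------------------------------------------------------------

@dataclass
class QuantileProfile:
    """Coefficient path of one design column across the quantile grid."""

    snp_id: str
    tau_grid: np.ndarray
    beta_path: np.ndarray
    se_path: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    process_cov: np.ndarray
    objectives: np.ndarray
    sparsities: np.ndarray
    hs_chi2: float = np.nan
    hs_df: int = 0
    hs_p: float = np.nan
    linear_beta: float = np.nan
    linear_se: float = np.nan
    linear_p: float = np.nan
    complete: bool = True
    coefficients: np.ndarray = field(default=None, repr=False)  # per-tau full vectors


def quantile_process(y, X, tau_grid=None, snp_column: int = -1,
                     snp_id: str = "", se_method: str = "iid",
                     n_boot: int = 200, seed: int | None = None,
                     ci_level: float = 0.95) -> QuantileProfile:
    """Fit the quantile-coefficient process for one design column.

    Pointwise variances use the iid-error sparsity form

        Var(beta_g(tau)) = tau (1-tau) s(tau)^2 [(X'X)^{-1}]_gg

    and the cross-level covariance

        Cov(beta_g(ti), beta_g(tj)) = (min(ti,tj) - ti tj) s(ti) s(tj)
                                       [(X'X)^{-1}]_gg.

    ``se_method``:
      * ``"iid"``   — the sparsity form above (default; matches the classical
        "sparsity method" confidence intervals),
      * ``"nid"``   — Hendricks–Koenker sandwich allowing covariate-dependent
        error densities,
      * ``"bootstrap"`` — resample individuals ``n_boot`` times and take the
        empirical covariance of the paths.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if tau_grid is None:
        tau_grid = DEFAULT_TAU_GRID
    tau_grid = np.asarray(tau_grid, dtype=float)
    if not (np.all(np.diff(tau_grid) > 0) and 0 < tau_grid[0] and tau_grid[-1] < 1):
        raise ValueError("tau grid must be strictly increasing within (0, 1)")
    g = snp_column % p
    m = len(tau_grid)

    xtx_inv = np.linalg.inv(X.T @ X)
    v_gg = xtx_inv[g, g]

    betas = np.empty((m, p))
    objectives = np.empty(m)
    sparsities = np.empty(m)
    complete = True
    try:
        for i, tau in enumerate(tau_grid):
            fit = fit_quantile(y, X, tau)
            betas[i] = fit.coefficients
            objectives[i] = fit.objective
            sparsities[i] = sparsity_estimate(fit, n)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover
        logger.warning("quantile process for %s incomplete: %s", snp_id, exc)
        complete = False

    beta_path = betas[:, g]
    if se_method == "iid":
        ti = tau_grid[:, None]
        tj = tau_grid[None, :]
        cov = (np.minimum(ti, tj) - ti * tj) * np.outer(sparsities, sparsities) * v_gg
    elif se_method == "nid":
        cov = _nid_process_cov(y, X, tau_grid, betas, g, n)
    elif se_method == "bootstrap":
        cov = _bootstrap_process_cov(y, X, tau_grid, g, n_boot, seed)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    se = np.sqrt(np.diag(cov))
    zq = norm.ppf(0.5 + ci_level / 2.0)
    profile = QuantileProfile(
        snp_id=snp_id, tau_grid=tau_grid, beta_path=beta_path, se_path=se,
        ci_low=beta_path - zq * se, ci_high=beta_path + zq * se,
        process_cov=cov, objectives=objectives, sparsities=sparsities,
        complete=complete, coefficients=betas,
    )
    if complete:
        w, df, pval = wald_heteroscedasticity(profile)
        profile.hs_chi2, profile.hs_df, profile.hs_p = w, df, pval
        lb, lse, lp_ = linear_effect(y, X, coef_index=g)
        profile.linear_beta, profile.linear_se, profile.linear_p = lb, lse, lp_
    return profile


def _nid_process_cov(y, X, tau_grid, betas, g, n):
    """Hendricks–Koenker sandwich covariance of the coefficient process."""
    xtx = X.T @ X
    rows = []
    for i, tau in enumerate(tau_grid):
        h = hall_sheather_bandwidth(tau, n)
        h = min(h, tau - 0.5 / n, 1.0 - tau - 0.5 / n)
        bhi = fit_quantile(y, X, min(tau + h, 1 - 0.25 / n)).coefficients
        blo = fit_quantile(y, X, max(tau - h, 0.25 / n)).coefficients
        di = X @ (bhi - blo)
        fi = np.clip((2.0 * h) / np.maximum(di, 1e-10), 0, None)
        H = (X * fi[:, None]).T @ X
        rows.append(np.linalg.solve(H, np.eye(len(H)))[g])
    cov = np.empty((len(tau_grid), len(tau_grid)))
    for i, ti in enumerate(tau_grid):
        for j, tj in enumerate(tau_grid):
            cov[i, j] = (min(ti, tj) - ti * tj) * rows[i] @ xtx @ rows[j]
    return cov


def _bootstrap_process_cov(y, X, tau_grid, g, n_boot, seed):
    rng = np.random.default_rng(seed)
    n = len(y)
    paths = np.empty((n_boot, len(tau_grid)))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        Xb, yb = X[idx], y[idx]
        if np.linalg.matrix_rank(Xb) < X.shape[1]:
            idx = rng.integers(0, n, n)
            Xb, yb = X[idx], y[idx]
        for i, tau in enumerate(tau_grid):
            paths[b, i] = fit_quantile(yb, Xb, tau).coefficients[g]
    return np.cov(paths, rowvar=False)


# ---------------------------------------------------------------------------
# Wald test for heteroscedasticity (quantile-varying effect)
# ---------------------------------------------------------------------------

def wald_heteroscedasticity(profile: QuantileProfile,
                            rank_rtol: float = 1e-10) -> tuple[float, int, float]:
    """Joint Wald test that the coefficient path is flat across the grid.

    The contrast takes consecutive differences of the path (m-1 x m); the
    statistic is W = (Db)' (D Sigma D')^+ (Db) with degrees of freedom equal
    to the rank of the contrast covariance (pseudo-inverse with relative
    tolerance ``rank_rtol``).  Rejection means the genetic effect differs
    across quantiles of the phenotype.
    """
    if not profile.complete:
        raise ValueError("cannot test an incomplete profile")
    b = profile.beta_path
    m = len(b)
    D = -np.eye(m - 1, m) + np.eye(m - 1, m, k=1)
    d = D @ b
    S = D @ profile.process_cov @ D.T
    svals = np.linalg.svd(S, compute_uv=False)
    tol = svals[0] * rank_rtol if svals[0] > 0 else 0.0
    df = int(np.sum(svals > tol))
    if df == 0:
        raise ValueError("contrast covariance has zero rank")
    S_pinv = np.linalg.pinv(S, rcond=rank_rtol)
    w = float(d @ S_pinv @ d)
    p = float(chi2.sf(w, df))
    return w, df, max(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# Koenker–Machado goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class R1Result:
    raw: float
    adjusted: float
    floored: bool = False


def r1_adj(v_full: float, v_restricted: float, n: int,
           p_full: int, p_restricted: int) -> R1Result:
    """Koenker–Machado R1 for nested quantile fits, with a df adjustment.

    raw      = 1 - V_full / V_restricted
    adjusted = 1 - (V_full / (n - p_full)) / (V_restricted / (n - p_restricted))

    The adjusted value is floored at 0 (flagged) since the df correction can
    push it below zero for a worthless added predictor.
    """
    if v_full < 0 or v_restricted < 0:
        raise ValueError("check-loss values must be nonnegative")
    if v_restricted < v_full - 1e-9 * (1.0 + v_full):
        raise ValueError("V_restricted < V_full: models do not look nested")
    if n <= p_full:
        raise ValueError("need n > p_full")
    if v_restricted == 0.0:
        if v_full > 0.0:
            raise ValueError("V_restricted = 0 with V_full > 0: not nested")
        return R1Result(raw=0.0, adjusted=0.0)
    raw = 1.0 - v_full / v_restricted
    adjusted = 1.0 - (v_full / (n - p_full)) / (v_restricted / (n - p_restricted))
    floored = adjusted < 0.0
    return R1Result(raw=raw, adjusted=max(adjusted, 0.0), floored=floored)


def delta_r2_profile(y, X_base, genotypes, snp_sets: dict, tau_grid=None):
    """Delta R1_adj of adding each SNP set to the base covariate model, per tau.

    ``genotypes`` is an n x m dosage array; ``snp_sets`` maps a label to a
    list of its column indices.  For every set and every tau the improvement
    is R1_adj(base + set) - R1_adj(base), both measured against the
    intercept-only fit from the respective minimised check losses.
    Returns ``{label: array over tau_grid}``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X_base = np.atleast_2d(np.asarray(X_base, dtype=float))
    if tau_grid is None:
        tau_grid = DEFAULT_TAU_GRID
    tau_grid = np.asarray(tau_grid, dtype=float)
    n, p_base = X_base.shape
    ones = np.ones((n, 1))

    for label, cols in snp_sets.items():
        if len(set(cols)) < len(cols):
            raise ValueError(f"SNP set {label!r} lists a column twice")

    v0 = np.array([fit_quantile(y, ones, t).objective for t in tau_grid])
    v_base = np.array([fit_quantile(y, X_base, t).objective for t in tau_grid])
    out = {}
    for label, cols in snp_sets.items():
        cols = list(cols)
        if not cols:
            out[label] = np.zeros(len(tau_grid))
            continue
        G = np.asarray(genotypes, dtype=float)[:, cols]
        X_full = np.column_stack([X_base, G])
        p_full = X_full.shape[1]
        deltas = np.empty(len(tau_grid))
        for i, tau in enumerate(tau_grid):
            v_full = fit_quantile(y, X_full, tau).objective
            r_full = r1_adj(v_full, v0[i], n, p_full, 1).adjusted
            r_base = r1_adj(min(v_base[i], v0[i]), v0[i], n, p_base, 1).adjusted
            deltas[i] = r_full - r_base
        out[label] = deltas
    return out


# ---------------------------------------------------------------------------
# companion linear (OLS) effect
# ---------------------------------------------------------------------------

def linear_effect(y, X, coef_index: int = -1) -> tuple[float, float, float]:
    """OLS effect size with classical SE and a t-based p value (n-p df)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    j = coef_index % p
    if np.ptp(X[:, j]) == 0.0:
        raise ValueError("dosage column has zero variance")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = max(rss, 0.0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[j, j]))
    if se == 0.0:
        return float(beta[j]), 0.0, 0.0 if beta[j] != 0 else 1.0
    tval = beta[j] / se
    return float(beta[j]), se, float(2.0 * t_dist.sf(abs(tval), df))
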