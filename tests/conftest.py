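"""Shared fixtures and independent oracles."""

import itertools

import numpy as np
import pytest

from quantgwas import check_loss
from quantgwas.simulate import SimulationConfig, SnpSpec, simulate_cohort


def brute_force_check_loss(y, X, tau):
    """Exhaustive basic-solution oracle for tiny quantile-regression fits.

    An optimal check-loss solution interpolates p observations (a vertex of
    the LP); enumerate every nonsingular p-subset and return the smallest
    objective.  Independent of the LP solver.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    best = np.inf
    for subset in itertools.combinations(range(n), p):
        Xs = X[list(subset)]
        if abs(np.linalg.det(Xs)) < 1e-12:
            continue
        beta = np.linalg.solve(Xs, y[list(subset)])
        obj = float(np.sum(check_loss(y - X @ beta, tau)))
        best = min(best, obj)
    return best


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 600-child cohort with one scale and one location SNP."""
    cfg = SimulationConfig(
        n_individuals=600,
        seed=11,
        snp_specs=[
            SnpSpec("scale1", 1, 1000, 0.3, beta_loc=0.0, gamma_scale=0.2),
            SnpSpec("loc1", 2, 2000, 0.3, beta_loc=0.08, gamma_scale=0.0),
        ],
        n_null_snps=20,
    )
    return simulate_cohort(cfg)
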