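"""Independent oracles used by the test suite.

These deliberately avoid every closed form in ``kindisp.analytics``: the
ESS dispersal oracle computes invasion fitness of a rare mutant lineage
as the dominant eigenvalue of a branching process over patch states, and
the permutation oracle enumerates all orderings exhaustively.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom


def invasion_fitness(xm: float, xr: float, n: int, c: float) -> float:
    """Growth rate of a rare mutant dispersal lineage in a resident population.

    Infinite island model, deterministic (large-k) juvenile pools.  A patch
    currently holding j of n mutant breeders contributes a Binomial(n, q_j)
    number of mutant breeders to itself next generation, where q_j is the
    mutant share of the local candidate pool, plus singleton colonists in
    other patches from its surviving emigrants.  Invasion fitness is the
    dominant eigenvalue of the resulting mean matrix over states j = 1..n.
    """
    imm = (1.0 - c) * xr  # immigrant juvenile mass per capita
    A = np.zeros((n, n))
    for j in range(1, n + 1):
        p = j / n
        stay_m = p * (1.0 - xm)
        stay_r = (1.0 - p) * (1.0 - xr)
        q = stay_m / (stay_m + stay_r + imm)
        A[:, j - 1] = binom.pmf(np.arange(1, n + 1), n, q)
        A[0, j - 1] += j * xm * (1.0 - c) / ((1.0 - xr) + imm)
    return float(np.linalg.eigvals(A).real.max())


def best_response_dispersal(xr: float, n: int, c: float) -> float:
    res = minimize_scalar(
        lambda xm: -invasion_fitness(xm, xr, n, c),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-11},
    )
    return float(res.x)


def ess_dispersal(n: int, c: float, tol: float = 1e-9) -> float:
    """Damped best-response iteration to the uninvadable dispersal rate."""
    x = 0.5
    for _ in range(500):
        b = best_response_dispersal(x, n, c)
        x_new = 0.5 * (x + b)
        if abs(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def exact_permutation_p(x, A) -> float:
    """Exact one-tailed (negative) permutation p-value for Pearson's r.

    Enumerates all len(A)! permutations; feasible for <= 7 points.
    p = #(r_perm <= r_obs) / n!, the exhaustive analogue of the Monte
    Carlo estimator.
    """
    x = np.asarray(x, float)
    A = np.asarray(A, float)
    xc = x - x.mean()
    r_obs = _pearson(xc, A - A.mean())
    hits = 0
    total = 0
    for perm in itertools.permutations(A):
        r = _pearson(xc, np.asarray(perm) - A.mean())
        if r <= r_obs + 1e-12:
            hits += 1
        total += 1
    return hits / total


def _pearson(xc: np.ndarray, yc: np.ndarray) -> float:
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
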