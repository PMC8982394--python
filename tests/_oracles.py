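"""Independent oracles used by the test suite.

Everything here deliberately avoids the code paths it checks: the KS
null distribution is enumerated combinatorially, and the multinomial
maximum-likelihood fit is redone with a derivative-free simplex search.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
from scipy.optimize import minimize


def enumerate_ks_null(n1: int, n2: int) -> dict[int, Fraction]:
    """Exact null distribution of the two-sample KS statistic.

    Enumerates every interleaving of n1 + n2 tie-free observations and
    records the path maximum of |i*n2 - j*n1| (the statistic in units
    of 1/(n1*n2)).  Returns ``P(D >= h/(n1*n2))`` for every achievable
    integer level h, as exact fractions.
    """
    total = comb(n1 + n2, n1)
    tail_counts: dict[int, int] = {}
    for first_positions in itertools.combinations(range(n1 + n2), n1):
        chosen = set(first_positions)
        i = j = 0
        peak = 0
        for step in range(n1 + n2):
            if step in chosen:
                i += 1
            else:
                j += 1
            peak = max(peak, abs(i * n2 - j * n1))
        tail_counts[peak] = tail_counts.get(peak, 0) + 1
    levels = sorted(tail_counts)
    sf: dict[int, Fraction] = {}
    running = 0
    for level in reversed(levels):
        running += tail_counts[level]
        sf[level] = Fraction(running, total)
    return sf


def simplex_ml_fit(counts, design, spec, maxiter: int = 60_000) -> np.ndarray:
    """Multinomial ML fit by Nelder-Mead on the log-likelihood.

    A derivative-free check on the scoring iteration: maximizes
    ``sum N_ij log(1/3 + X_i theta)`` over the free parameters with a
    barrier against leaving the probability simplex.
    """
    free = spec.free_mask
    Xf = design.per_cross[:, :, free]
    N = counts.counts

    def negll(theta: np.ndarray) -> float:
        p = design.baseline + Xf @ theta
        if np.any(p <= 1e-9) or np.any(p >= 1 - 1e-9):
            return 1e12
        return -float((N * np.log(p)).sum())

    result = minimize(
        negll, np.zeros(int(free.sum())), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13,
                 "maxiter": maxiter, "maxfev": maxiter})
    assert result.fun < 1e12, "simplex search left the probability simplex"
    return result.x
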