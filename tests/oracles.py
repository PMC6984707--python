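"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, direct summation,
closed forms) and shares no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import product
from math import comb, log

import numpy as np


def brute_count_combinations(min_total: int, max_total: int) -> int:
    """Exhaustive double loop over all 11 x 3^5 Alda item tuples."""
    count = 0
    for a in range(11):
        for bs in product(range(3), repeat=5):
            if min_total <= max(0, a - sum(bs)) <= max_total:
                count += 1
    return count


def poly_b_sum_counts() -> dict:
    """Coefficients of (1 + x + x^2)^5 via explicit polynomial multiplication."""
    coeffs = [1]
    for _ in range(5):
        new = [0] * (len(coeffs) + 2)
        for i, c in enumerate(coeffs):
            for j in range(3):
                new[i + j] += c
        coeffs = new
    return dict(enumerate(coeffs))


def brute_discrete_mi(joint: np.ndarray) -> float:
    """Direct double summation of p * log(p / (px * py)), in nats."""
    joint = np.asarray(joint, dtype=float)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    total = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            p = joint[i, j]
            if p > 0:
                total += p * log(p / (px[i] * py[j]))
    return total


def binary_entropy(p: float) -> float:
    """H(p) in nats."""
    if p in (0.0, 1.0):
        return 0.0
    return -p * log(p) - (1 - p) * log(1 - p)


def gaussian_mi(r: float) -> float:
    """Closed-form MI of a bivariate normal with correlation r, in nats."""
    return -0.5 * log(1.0 - r * r)


def brute_nchg_sf(t, total: int, n_success: int, n_draws: int, eta: float):
    """Survival function of Fisher's noncentral hypergeometric distribution.

    Direct summation of the unnormalized likelihood weights
    C(n_success, k) * C(total - n_success, n_draws - k) * eta^k over the
    support, in log space for numerical stability at large eta.
    """
    lo = max(0, n_success + n_draws - total)
    hi = min(n_success, n_draws)
    support = np.arange(lo, hi + 1)
    logw = np.array([
        log(comb(n_success, k)) + log(comb(total - n_success, n_draws - k))
        + k * log(eta)
        for k in support
    ])
    w = np.exp(logw - logw.max())
    w /= w.sum()
    t = np.atleast_1d(t)
    sf = np.array([w[support > ti].sum() for ti in t])
    return sf if sf.size > 1 else float(sf[0])
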