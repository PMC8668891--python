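"""Brute-force reference implementations used only by the tests.

Everything here is written as directly from the definitions as possible —
explicit loops over sequence pairs and sites — and stays independent of
the vectorized implementations in triabc.sumstats.
"""

import itertools
import math

import numpy as np


def pi_brute(matrix, L):
    """Mean pairwise difference per site by looping over all pairs."""
    n = matrix.shape[0]
    total = 0
    npairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int(np.sum(matrix[i] != matrix[j]))
        npairs += 1
    return total / npairs / L


def theta_w_brute(S, n, L):
    a = sum(1.0 / i for i in range(1, n))
    return S / (a * L)


def tajima_d_brute(k, S, n):
    """Tajima (1989) constants computed step by step."""
    if S == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (k - S / a1) / math.sqrt(var)


def dxy_brute(mat_x, mat_y, L):
    total = 0
    npairs = 0
    for i in range(mat_x.shape[0]):
        for j in range(mat_y.shape[0]):
            total += int(np.sum(mat_x[i] != mat_y[j]))
            npairs += 1
    return total / npairs / L


def da_brute(mat_x, mat_y, L):
    return dxy_brute(mat_x, mat_y, L) - (pi_brute(mat_x, L) + pi_brute(mat_y, L)) / 2


def fst_brute(mat_x, mat_y, L):
    """1 - pi_within / pi_total with pi_total from the pooled sample."""
    pooled = np.vstack([mat_x, mat_y])
    pi_total = pi_brute(pooled, L)
    if pi_total <= 0:
        return float("nan")
    pi_within = (pi_brute(mat_x, L) + pi_brute(mat_y, L)) / 2
    return 1 - pi_within / pi_total


def abba_baba_brute(p1, p2, p3):
    num = 0.0
    den = 0.0
    for a, b, c in zip(p1, p2, p3):
        abba = (1 - a) * b * c
        baba = a * (1 - b) * c
        num += abba - baba
        den += abba + baba
    if den == 0:
        return float("nan"), num, den
    return num / den, num, den


def site_patterns_brute(mat_x, mat_y):
    """Per-site classification by explicit case analysis."""
    shared = fixed = excl_x = excl_y = 0
    for j in range(mat_x.shape[1]):
        ax = set(mat_x[:, j].tolist())
        ay = set(mat_y[:, j].tolist())
        if len(ax) == 2 and len(ay) == 2:
            shared += 1
        elif len(ax) == 1 and len(ay) == 1 and ax != ay:
            fixed += 1
        elif len(ax) == 2 and len(ay) == 1:
            excl_x += 1
        elif len(ax) == 1 and len(ay) == 2:
            excl_y += 1
    return shared, fixed, excl_x, excl_y


def random_pop_matrices(rng, max_n=6, max_s=10):
    """Three random 0/1 population matrices sharing max_s segregating sites."""
    S = rng.integers(1, max_s + 1)
    mats = []
    for _ in range(3):
        n = rng.integers(2, max_n + 1)
        mats.append(rng.integers(0, 2, size=(n, S)).astype(np.int8))
    return mats
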