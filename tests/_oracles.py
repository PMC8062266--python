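"""Independent oracles used by the test suite.

Each function here re-derives a quantity by a route deliberately different
from the package implementation (dense grid scans, exact rational
arithmetic, textbook formulas), so agreement is evidence rather than
tautology.
"""

from fractions import Fraction
from math import comb

import numpy as np

from cellclock.curve import evaluate


def grid_scan_invert(curve, delta, window, step=0.001):
    """Brute-force inversion: scan a dense year grid and report sign changes
    of curve - delta (midpoint of the bracketing step)."""
    lo, hi = window
    years = np.arange(lo, hi + step / 2, step)
    years[-1] = min(years[-1], hi)
    f = np.asarray(evaluate(curve, years)) - delta
    out = []
    for y0, y1, f0, f1 in zip(years, years[1:], f, f[1:]):
        if f0 == 0.0:
            out.append(y0)
        elif f0 * f1 < 0:
            out.append(0.5 * (y0 + y1))
    if f[-1] == 0.0:
        out.append(years[-1])
    # merge near-duplicates from exact-zero hits
    merged = []
    for y in out:
        if not merged or y - merged[-1] > 2 * step:
            merged.append(y)
    return merged


def fisher_bruteforce(table):
    """Two-sided Fisher p by exhaustive enumeration with exact rationals."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


def pearson_distance_formula(x):
    """1 - r from the textbook covariance/correlation formulas, pairwise."""
    x = np.asarray(x, dtype=float)
    n_samples = x.shape[0]
    d = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(n_samples):
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            r = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
            d[i, j] = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d
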