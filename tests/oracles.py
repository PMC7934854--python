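"""Independent numerical oracles used by the test suite.

These deliberately avoid the implementation paths they check: exhaustive
search for Otsu, exact integer enumeration for the hypergeometric tail, and
quadrature of the raw densities for t/F tail probabilities.
"""

from fractions import Fraction
from math import comb, gamma, pi, sqrt

import numpy as np
from scipy import integrate


def brute_force_otsu(vals, nbins=256):
    """Exhaustive between-class-variance maximization over all bin cuts."""
    lo, hi = vals.min(), vals.max()
    hist, edges = np.histogram(vals, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_v = None, -np.inf
    total = hist.sum()
    for t in range(nbins - 1):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * centers[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:  # strict: ties stay at the lowest candidate
            best_v, best_t = v, t
    return edges[best_t + 1]


def exact_hypergeom_upper_tail(N, K, n, k):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact integer arithmetic."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(min(total, Fraction(1)))


def t_two_tailed_by_quadrature(t, df):
    def density(x):
        return (
            gamma((df + 1) / 2)
            / (sqrt(df * pi) * gamma(df / 2))
            * (1 + x * x / df) ** (-(df + 1) / 2)
        )

    tail, _ = integrate.quad(density, abs(t), np.inf)
    return 2 * tail


def f_upper_tail_by_quadrature(f, d1, d2):
    def density(x):
        b = gamma(d1 / 2) * gamma(d2 / 2) / gamma((d1 + d2) / 2)
        return (
            ((d1 / d2) ** (d1 / 2)) * x ** (d1 / 2 - 1) * (1 + d1 * x / d2) ** (-(d1 + d2) / 2) / b
        )

    tail, _ = integrate.quad(density, f, np.inf)
    return tail
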