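"""Independent reference implementations used only to check the package.

Each oracle is coded directly from first principles (exact rational
arithmetic, scalar sums over published formulas, numerical integration)
and never calls the code path it validates.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------
# Fisher exact test: exact-rational two-sided hypergeometric sum
# ---------------------------------------------------------------------

def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by exact enumeration.

    Sums hypergeometric point probabilities <= the observed table's
    probability, compared with exact rationals so ties are unambiguous.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = math.comb(n, c1)

    def weight(x: int) -> int:
        return math.comb(r1, x) * math.comb(r2, c1 - x)

    w_obs = weight(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(weight(x) for x in range(lo, hi + 1) if weight(x) <= w_obs)
    return float(Fraction(total, denom))


# ---------------------------------------------------------------------
# Weir-Cockerham 1984: scalar per-locus variance components
# ---------------------------------------------------------------------

def wc_theta_scalar(genotypes_by_group: list) -> float:
    """Theta-hat for one locus from per-group lists of diploid dosages.

    Direct scalar transcription of the 1984 two-allele variance
    components (a: among groups, b: among individuals within groups,
    c: within individuals), with no vectorisation shared with the
    package implementation.
    """
    groups = [np.asarray(g, dtype=float) for g in genotypes_by_group]
    groups = [g[~np.isnan(g)] for g in groups]
    groups = [g for g in groups if len(g) >= 2]
    r = len(groups)
    if r < 2:
        return float("nan")
    n_i = [len(g) for g in groups]
    p_i = [g.sum() / (2 * len(g)) for g in groups]
    h_i = [(g == 1).mean() for g in groups]
    nbar = sum(n_i) / r
    nsum = sum(n_i)
    nc = (nsum - sum(ni * ni for ni in n_i) / nsum) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n_i, p_i)) / nsum
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n_i, h_i)) / nsum

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


# ---------------------------------------------------------------------
# Benjamini-Hochberg: literal step-up definition
# ---------------------------------------------------------------------

def bh_stepup_reference(p: np.ndarray) -> np.ndarray:
    """q_(i) = min_{j>=i} p_(j) m / j, built with an explicit loop."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return q


# ---------------------------------------------------------------------
# Tajima's D: direct 1989 formula for one window
# ---------------------------------------------------------------------

def tajimas_d_reference(freqs: list, n_seq: int) -> float:
    """D from per-site allele frequencies and a fixed sequence count."""
    S = sum(1 for f in freqs if 0.0 < f < 1.0)
    if S == 0:
        return float("nan")
    pi = sum(
        2.0 * f * (1.0 - f) * n_seq / (n_seq - 1.0) for f in freqs if 0.0 < f < 1.0
    )
    a1 = sum(1.0 / i for i in range(1, n_seq))
    a2 = sum(1.0 / i**2 for i in range(1, n_seq))
    b1 = (n_seq + 1.0) / (3.0 * (n_seq - 1.0))
    b2 = 2.0 * (n_seq**2 + n_seq + 3.0) / (9.0 * n_seq * (n_seq - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n_seq + 2.0) / (a1 * n_seq) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return (pi - S / a1) / math.sqrt(var)


# ---------------------------------------------------------------------
# Studentized range upper tail: numerical double integration
# ---------------------------------------------------------------------

def studentized_range_sf_reference(q: float, k: int, df: float) -> float:
    """P(Q > q) for the studentized range by direct quadrature.

    Outer integral over the scale s ~ sqrt(chi2_df / df), inner over
    the location of the minimum of k standard normals.
    """
    from scipy import integrate, stats

    def inner(s: float) -> float:
        def f(z: float) -> float:
            return stats.norm.pdf(z) * (
                stats.norm.cdf(z) - stats.norm.cdf(z - q * s)
            ) ** (k - 1)

        val, _ = integrate.quad(f, -8.0, 8.0, limit=200)
        return k * val

    # density of s = sqrt(X/df), X ~ chi2_df
    def outer(s: float) -> float:
        x = s * s * df
        dens = stats.chi2.pdf(x, df) * 2.0 * s * df
        return dens * inner(s)

    cdf, _ = integrate.quad(outer, 1e-8, 10.0, limit=200)
    return 1.0 - cdf


# ---------------------------------------------------------------------
# Hypergeometric enrichment: exact-rational upper tail
# ---------------------------------------------------------------------

def hypergeom_sf_exact(k_overlap: int, n: int, n_a: int, n_b: int) -> float:
    """P(X >= k) for overlap of a size-n_b draw with a size-n_a subset."""
    denom = math.comb(n, n_b)
    total = sum(
        math.comb(n_a, k) * math.comb(n - n_a, n_b - k)
        for k in range(k_overlap, min(n_a, n_b) + 1)
    )
    return float(Fraction(total, denom))
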