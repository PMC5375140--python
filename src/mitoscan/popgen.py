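"""Core population-genetic statistics.

Everything downstream of genotype QC rests on the functions here:

* per-locus summaries (minor-allele frequency, observed and unbiased
  expected heterozygosity, call rate);
* the Weir–Cockerham (1984) variance-components F_ST estimator,
  vectorised across loci with per-locus, per-group sample sizes so that
  missing genotypes are handled exactly;
* a two-sided Fisher exact test on 2x2 allele-count tables;
* pairwise linkage disequilibrium on unphased genotypes (r² from dosage
  correlation, D' from a two-locus phase-unknown EM);
* Tajima's D in fixed-width physical windows;
* the Benjamini–Hochberg step-up FDR procedure.

Dosage convention: entries count copies of the alternate allele
(0/1/2), NaN is missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GenotypeMatrix

__all__ = [
    "locus_summaries",
    "weir_cockerham_fst",
    "wc_theta",
    "fisher_exact_allele",
    "ld_pairs",
    "ld_scan",
    "tajimas_d",
    "bh_fdr",
]


# ---------------------------------------------------------------------
# per-locus summaries
# ---------------------------------------------------------------------

def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per locus over non-missing calls."""
    typed = ~np.isnan(dosages)
    n = typed.sum(axis=0)
    ac = np.nansum(dosages, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, ac / (2.0 * n), np.nan)


def locus_summaries(gm: GenotypeMatrix) -> pd.DataFrame:
    """MiAF, Ho, He (unbiased) and call rate per locus.

    MiAF is the minor-allele frequency over all typed individuals
    regardless of group; He uses the small-sample correction
    ``2p(1-p) * 2n/(2n-1)`` with ``n`` the number of typed diploids.
    """
    d = gm.dosages
    typed = ~np.isnan(d)
    n = typed.sum(axis=0).astype(float)
    p = allele_frequencies(d)
    miaf = np.minimum(p, 1.0 - p)
    het = np.nansum(d == 1, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / n, np.nan)
        he = np.where(
            n > 0,
            2.0 * p * (1.0 - p) * (2.0 * n) / np.maximum(2.0 * n - 1.0, 1.0),
            np.nan,
        )
    return pd.DataFrame(
        {
            "locus_id": gm.loci["locus_id"].to_numpy(),
            "miaf": miaf,
            "ho": ho,
            "he": he,
            "call_rate": n / gm.n_individuals,
        }
    )


# ---------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------

def _group_indicator(labels: np.ndarray) -> tuple[np.ndarray, list]:
    groups = list(pd.unique(pd.Series(labels)))
    G = np.stack([(labels == g).astype(float) for g in groups])
    return G, groups


def wc_theta(
    dosages: np.ndarray, labels: np.ndarray, min_per_group: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham variance components.

    Returns ``(theta, a, b, c)`` arrays of length ``n_loci``.  A group
    contributes at a locus only if it has at least ``min_per_group``
    typed individuals there; loci with fewer than two contributing
    groups, or with ``a + b + c == 0`` (monomorphic across groups), get
    ``theta = NaN``.  Negative estimates are reported as-is.
    """
    labels = np.asarray(labels)
    G, _ = _group_indicator(labels)
    typed = (~np.isnan(dosages)).astype(float)
    filled = np.nan_to_num(dosages)
    het = np.where(np.isnan(dosages), 0.0, (dosages == 1).astype(float))

    n_gl = G @ typed            # typed diploids per group x locus
    ac_gl = G @ filled          # alt-allele count
    het_gl = G @ het            # heterozygote count

    contrib = n_gl >= min_per_group
    n = np.where(contrib, n_gl, 0.0)
    r = contrib.sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        p_gl = np.where(contrib, ac_gl / np.maximum(2.0 * n_gl, 1.0), 0.0)
        h_gl = np.where(contrib, het_gl / np.maximum(n_gl, 1.0), 0.0)

        ntot = n.sum(axis=0)
        nbar = ntot / np.maximum(r, 1.0)
        # n_c corrects for unequal group sizes
        n_c = (ntot - (n**2).sum(axis=0) / np.maximum(ntot, 1.0)) / np.maximum(
            r - 1.0, 1.0
        )
        pbar = (n * p_gl).sum(axis=0) / np.maximum(ntot, 1.0)
        s2 = (n * (p_gl - pbar) ** 2).sum(axis=0) / (
            np.maximum(r - 1.0, 1.0) * np.maximum(nbar, 1.0)
        )
        hbar = (n * h_gl).sum(axis=0) / np.maximum(ntot, 1.0)

        inner = pbar * (1.0 - pbar) - (r - 1.0) / np.maximum(r, 1.0) * s2
        a = nbar / np.maximum(n_c, 1e-300) * (
            s2 - (inner - hbar / 4.0) / np.maximum(nbar - 1.0, 1e-300)
        )
        b = nbar / np.maximum(nbar - 1.0, 1e-300) * (
            inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

        denom = a + b + c
        theta = np.where(denom != 0.0, a / np.where(denom == 0.0, 1.0, denom), np.nan)

    bad = (r < 2) | (denom == 0.0)
    theta = np.where(bad, np.nan, theta)
    a = np.where(r < 2, np.nan, a)
    b = np.where(r < 2, np.nan, b)
    c = np.where(r < 2, np.nan, c)
    return theta, a, b, c


def weir_cockerham_fst(
    gm: GenotypeMatrix, labels: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Per-locus theta plus the multilocus ratio-of-sums estimate."""
    theta, a, b, c = wc_theta(gm.dosages, np.asarray(labels))
    ok = ~np.isnan(a)
    denom = np.nansum(a[ok] + b[ok] + c[ok])
    multi = float(np.nansum(a[ok]) / denom) if denom != 0 else float("nan")
    table = pd.DataFrame(
        {"locus_id": gm.loci["locus_id"].to_numpy(), "fst": theta, "a": a, "b": b, "c": c}
    )
    return table, multi


# ---------------------------------------------------------------------
# Fisher exact allele-count test
# ---------------------------------------------------------------------

def fisher_exact_allele(gm: GenotypeMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Two-sided Fisher exact p per locus from minor/major x group allele counts.

    The minor allele is defined over all individuals jointly (it may be
    the majority allele within one group).  Tables with a zero margin
    give p = 1.
    """
    labels = np.asarray(labels)
    uniq = pd.unique(pd.Series(labels))
    if len(uniq) != 2:
        raise ValueError("fisher_exact_allele needs exactly two groups")
    d = gm.dosages
    typed = ~np.isnan(d)
    p_all = allele_frequencies(d)
    in1 = labels == uniq[0]

    alt1 = np.nansum(d[in1], axis=0)
    alt2 = np.nansum(d[~in1], axis=0)
    tot1 = 2.0 * typed[in1].sum(axis=0)
    tot2 = 2.0 * typed[~in1].sum(axis=0)

    pvals = np.ones(gm.n_loci)
    for j in range(gm.n_loci):
        # orient the table to the genome-wide minor allele
        if p_all[j] <= 0.5:
            table = [[alt1[j], alt2[j]], [tot1[j] - alt1[j], tot2[j] - alt2[j]]]
        else:
            table = [[tot1[j] - alt1[j], tot2[j] - alt2[j]], [alt1[j], alt2[j]]]
        t = np.asarray(table, dtype=int)
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            pvals[j] = 1.0
        else:
            pvals[j] = sps.fisher_exact(t, alternative="two-sided")[1]
    return pd.DataFrame({"locus_id": gm.loci["locus_id"].to_numpy(), "fisher_p": pvals})


# ---------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------

def _em_haplotype_freqs(
    counts: np.ndarray, tol: float = 1e-12, max_iter: int = 2000
) -> tuple[np.ndarray, np.ndarray]:
    """Two-locus phase-unknown EM, vectorised over pairs.

    ``counts`` has shape ``(n_pairs, 3, 3)``: joint genotype counts with
    axis 1 the dosage at locus i and axis 2 at locus j.  Returns
    ``(f, converged)`` with ``f`` of shape ``(n_pairs, 4)`` holding the
    haplotype frequencies ``(f11, f10, f01, f00)`` where 1 denotes the
    alternate allele.  Only the double heterozygote is phase-ambiguous:
    its ``n`` copies split between coupling (1,1)+(0,0) and repulsion
    (1,0)+(0,1) resolutions in the E-step.
    """
    c = counts.astype(float)
    two_n = 2.0 * c.sum(axis=(1, 2))
    n_dh = c[:, 1, 1]
    # fixed haplotype-count contributions from unambiguous genotypes
    base11 = 2 * c[:, 2, 2] + c[:, 2, 1] + c[:, 1, 2]
    base10 = 2 * c[:, 2, 0] + c[:, 2, 1] + c[:, 1, 0]
    base01 = 2 * c[:, 0, 2] + c[:, 1, 2] + c[:, 0, 1]
    base00 = 2 * c[:, 0, 0] + c[:, 1, 0] + c[:, 0, 1]

    p = (base11 + base10 + n_dh) / np.maximum(two_n, 1.0)  # alt freq locus i
    q = (base11 + base01 + n_dh) / np.maximum(two_n, 1.0)  # alt freq locus j
    f = np.stack([p * q, p * (1 - q), (1 - p) * q, (1 - p) * (1 - q)], axis=1)

    converged = np.zeros(len(c), dtype=bool)
    for _ in range(max_iter):
        coupling = f[:, 0] * f[:, 3]
        repulsion = f[:, 1] * f[:, 2]
        denom = coupling + repulsion
        w = np.where(denom > 0, coupling / np.where(denom == 0, 1.0, denom), 0.5)
        e_dh = n_dh * w
        new = np.stack(
            [base11 + e_dh, base10 + n_dh - e_dh, base01 + n_dh - e_dh, base00 + e_dh],
            axis=1,
        ) / np.maximum(two_n, 1.0)[:, None]
        delta = np.abs(new - f).max(axis=1)
        f = new
        converged |= delta < tol
        if converged.all():
            break
    return f, converged


def _d_prime_from_freqs(f: np.ndarray) -> np.ndarray:
    p = f[:, 0] + f[:, 1]
    q = f[:, 0] + f[:, 2]
    d = f[:, 0] - p * q
    dmax_pos = np.minimum(p * (1 - q), (1 - p) * q)
    dmax_neg = np.minimum(p * q, (1 - p) * (1 - q))
    dmax = np.where(d >= 0, dmax_pos, dmax_neg)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(dmax > 0, d / np.where(dmax == 0, 1.0, dmax), 0.0)


def ld_pairs(
    gm: GenotypeMatrix, i_idx: np.ndarray, j_idx: np.ndarray, chunk: int = 20000
) -> pd.DataFrame:
    """r², D' and chi-square p for the given locus index pairs.

    r² is the squared Pearson correlation of dosages over individuals
    typed at both loci; D' comes from EM haplotype frequencies; the
    p-value is the one-degree chi-square on ``2 n r²`` gametes.
    Pairs with a monomorphic member (over the jointly typed set) are
    dropped.
    """
    i_idx = np.asarray(i_idx)
    j_idx = np.asarray(j_idx)
    d = gm.dosages
    loci = gm.loci
    frames = []
    for start in range(0, len(i_idx), chunk):
        ii = i_idx[start : start + chunk]
        jj = j_idx[start : start + chunk]
        x = d[:, ii]
        y = d[:, jj]
        both = ~np.isnan(x) & ~np.isnan(y)
        n = both.sum(axis=0).astype(float)
        xm = np.where(both, x, 0.0)
        ym = np.where(both, y, 0.0)
        sx = xm.sum(axis=0)
        sy = ym.sum(axis=0)
        sxx = (xm * xm).sum(axis=0)
        syy = (ym * ym).sum(axis=0)
        sxy = (xm * ym).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vx = sxx - sx * sx / n
            vy = syy - sy * sy / n
            cov = sxy - sx * sy / n
            r2 = np.where((vx > 0) & (vy > 0), cov**2 / (vx * vy), np.nan)

        counts = np.empty((len(ii), 3, 3))
        for a in range(3):
            xa = both & (x == a)
            for b in range(3):
                counts[:, a, b] = (xa & (y == b)).sum(axis=0)
        f, conv = _em_haplotype_freqs(counts)
        dprime = _d_prime_from_freqs(f)

        ok = ~np.isnan(r2)
        chi2 = 2.0 * n * np.nan_to_num(r2)
        p_ld = sps.chi2.sf(chi2, df=1)

        same = loci["scaffold"].to_numpy()[ii] == loci["scaffold"].to_numpy()[jj]
        dist = np.where(
            same,
            np.abs(loci["pos"].to_numpy()[jj] - loci["pos"].to_numpy()[ii]),
            -1,
        )
        frames.append(
            pd.DataFrame(
                {
                    "locus_i": loci["locus_id"].to_numpy()[ii],
                    "locus_j": loci["locus_id"].to_numpy()[jj],
                    "same_scaffold": same,
                    "distance_bp": dist,
                    "r2": r2,
                    "d_prime": dprime,
                    "p_ld": p_ld,
                    "em_converged": conv,
                }
            )[ok]
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(out):
        out["q_bh"] = bh_fdr(out["p_ld"].to_numpy())
    return out


def ld_scan(gm: GenotypeMatrix, window_snps: int = 50) -> pd.DataFrame:
    """All pairwise LD within a sliding window of ``window_snps`` SNPs.

    The window is counted in SNPs over the locus order (within and
    across scaffolds), i.e. pairs at index distance < ``window_snps``.
    """
    L = gm.n_loci
    ii, jj = [], []
    for off in range(1, min(window_snps, L)):
        idx = np.arange(L - off)
        ii.append(idx)
        jj.append(idx + off)
    if not ii:
        return pd.DataFrame()
    return ld_pairs(gm, np.concatenate(ii), np.concatenate(jj))


# ---------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------

def _tajima_constants(n_seq: int) -> dict:
    i = np.arange(1, n_seq)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n_seq + 1.0) / (3.0 * (n_seq - 1.0))
    b2 = 2.0 * (n_seq**2 + n_seq + 3.0) / (9.0 * n_seq * (n_seq - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n_seq + 2.0) / (a1 * n_seq) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d(gm: GenotypeMatrix, window_bp: int = 50) -> pd.DataFrame:
    """Tajima's D in non-overlapping ``window_bp`` windows per scaffold.

    Windows are 0-based half-open ``[k*w, (k+1)*w)``.  Within a window,
    S counts polymorphic sites, pi sums the unbiased per-site
    heterozygosity ``2p(1-p) * 2n/(2n-1)``, and the number of sequences
    is twice the minimum number of typed diploids across the window's
    sites (conservative under missing data).  D is undefined (NaN) when
    S = 0 or the variance term vanishes.
    """
    d = gm.dosages
    typed = (~np.isnan(d)).sum(axis=0)
    p = allele_frequencies(d)
    scaff = gm.loci["scaffold"].to_numpy()
    pos0 = gm.loci["pos"].to_numpy() - 1  # to 0-based
    win = pos0 // window_bp

    rows = []
    df = pd.DataFrame({"scaffold": scaff, "win": win, "idx": np.arange(gm.n_loci)})
    for (sc, w), grp in df.groupby(["scaffold", "win"], sort=False):
        idx = grp["idx"].to_numpy()
        seg = idx[(p[idx] > 0) & (p[idx] < 1) & (typed[idx] > 0)]
        S = len(seg)
        n_dip = int(typed[seg].min()) if S else 0
        if S == 0 or n_dip < 2:
            rows.append((sc, int(w) * window_bp, S, 0.0, np.nan))
            continue
        n_seq = 2 * n_dip
        pi = float(
            np.sum(2.0 * p[seg] * (1.0 - p[seg]) * n_seq / (n_seq - 1.0))
        )
        k = _tajima_constants(n_seq)
        var = k["e1"] * S + k["e2"] * S * (S - 1)
        D = (pi - S / k["a1"]) / np.sqrt(var) if var > 0 else np.nan
        rows.append((sc, int(w) * window_bp, S, pi, D))
    return pd.DataFrame(rows, columns=["scaffold", "window_start", "S", "pi", "D"])


# ---------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------

def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j, clipped at 1, mapped back
    to the input order.  Empty input returns an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
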