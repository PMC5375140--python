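"""Within-population F_ST scan between mitochondrial-haplotype groups.

The central computation: treat the two mt-haplotype carrier groups of
one population as artificial subpopulations, estimate a per-locus
Weir–Cockerham theta ("wF_ST"), and call outliers against a
heterozygosity-stratified permutation null — individuals are randomly
reassigned to two groups of the observed mt-group sizes, theta is
recomputed for every locus, and each locus is judged only against
permuted values from loci of similar expected heterozygosity (F_ST's
null dispersion depends on He).  One-sided upper-tail testing only:
outliers are loci with improbably *large* wF_ST.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GenotypeMatrix
from .popgen import bh_fdr, locus_summaries, wc_theta

logger = logging.getLogger(__name__)

__all__ = [
    "wfst_scan",
    "PermutationNull",
    "permutation_null",
    "empirical_p",
    "call_outliers",
    "scan_concordance",
    "fst_density_compare",
]


def _known_mt(gm: GenotypeMatrix, mt_labels=None) -> tuple[GenotypeMatrix, np.ndarray]:
    labels = np.asarray(mt_labels if mt_labels is not None else gm.mt_labels())
    known = np.isin(labels, ("north", "south"))
    if not known.all():
        logger.warning("excluding %d individuals with unknown mt-haplotype", (~known).sum())
        gm = gm.take_samples(known)
        labels = labels[known]
    if len(np.unique(labels)) != 2:
        raise ValueError("need both mt-haplotype groups present")
    return gm, labels


def wfst_scan(gm: GenotypeMatrix, mt_labels=None) -> pd.DataFrame:
    """Per-locus Weir–Cockerham theta between the two mt-haplotype groups."""
    gm, labels = _known_mt(gm, mt_labels)
    theta, _, _, _ = wc_theta(gm.dosages, labels)
    return pd.DataFrame({"locus_id": gm.loci["locus_id"].to_numpy(), "fst": theta})


@dataclass
class PermutationNull:
    """Pooled permuted theta values stratified by expected heterozygosity.

    ``bin_edges`` partition [0, 1]; ``bin_of_locus`` maps each locus to
    its (possibly merged) bin; ``null_values[b]`` holds the sorted
    permuted thetas pooled over all loci in bin ``b`` and all
    permutations.
    """

    n_permutations: int
    group_sizes: tuple
    bin_edges: np.ndarray
    bin_of_locus: np.ndarray
    null_values: list
    seed: int

    @property
    def n_bins(self) -> int:
        return len(self.null_values)


def _he_bin_edges(he: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count (quantile) bin edges over observed He, spanning [0, 1]."""
    qs = np.quantile(he[~np.isnan(he)], np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    edges[0], edges[-1] = 0.0, 1.0
    if len(edges) < 2:
        edges = np.array([0.0, 1.0])
    return edges


def permutation_null(
    gm: GenotypeMatrix,
    mt_labels=None,
    n_perm: int = 1000,
    he_bins: int = 10,
    seed: int = 0,
    min_bin_count: int = 200,
) -> PermutationNull:
    """Build the He-stratified permutation null of wF_ST.

    Each permutation draws a random two-group split of the individuals
    at the observed mt-group sizes (sampling without replacement) and
    recomputes theta for every locus; values pool into the He bin of
    the locus that produced them.  Bins ending up with fewer than
    ``min_bin_count`` values are merged with their neighbour.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for p-value resolution 0.01")
    gm, labels = _known_mt(gm, mt_labels)
    rng = np.random.default_rng(seed)
    n = gm.n_individuals
    uniq, counts = np.unique(labels, return_counts=True)
    n_a = int(counts[0])

    he = locus_summaries(gm)["he"].to_numpy()
    edges = _he_bin_edges(he, he_bins)
    bin_of_locus = np.clip(np.searchsorted(edges, he, side="right") - 1, 0, len(edges) - 2)

    per_bin: list[list[np.ndarray]] = [[] for _ in range(len(edges) - 1)]
    perm_labels = labels.copy()
    for _ in range(n_perm):
        order = rng.permutation(n)
        perm_labels[:] = uniq[1]
        perm_labels[order[:n_a]] = uniq[0]
        theta, _, _, _ = wc_theta(gm.dosages, perm_labels)
        ok = ~np.isnan(theta)
        for b in range(len(per_bin)):
            sel = ok & (bin_of_locus == b)
            if sel.any():
                per_bin[b].append(theta[sel].astype(np.float32))

    null_values = [
        np.sort(np.concatenate(v)) if v else np.array([], dtype=np.float32)
        for v in per_bin
    ]
    # merge sparse bins with their left neighbour (resolution guard)
    bin_map = np.arange(len(null_values))
    merged_values, merged_map = [], {}
    buffer = np.array([], dtype=np.float32)
    pending_bins: list[int] = []
    for b, vals in enumerate(null_values):
        buffer = np.concatenate([buffer, vals])
        pending_bins.append(b)
        if len(buffer) >= min_bin_count:
            idx = len(merged_values)
            merged_values.append(np.sort(buffer))
            for pb in pending_bins:
                merged_map[pb] = idx
            buffer = np.array([], dtype=np.float32)
            pending_bins = []
    if pending_bins:
        if merged_values:
            idx = len(merged_values) - 1
            merged_values[idx] = np.sort(np.concatenate([merged_values[idx], buffer]))
        else:
            idx = 0
            merged_values.append(np.sort(buffer))
        for pb in pending_bins:
            merged_map[pb] = idx
    bin_of_locus = np.array([merged_map[b] for b in bin_of_locus])

    return PermutationNull(
        n_permutations=n_perm,
        group_sizes=(n_a, n - n_a),
        bin_edges=edges,
        bin_of_locus=bin_of_locus,
        null_values=merged_values,
        seed=seed,
    )


def empirical_p(theta: np.ndarray, null: PermutationNull) -> np.ndarray:
    """One-sided upper-tail permutation p per locus: (b+1)/(m+1).

    ``b`` counts null values >= the observed theta within the locus's
    He bin of size ``m``; the add-one rule keeps p > 0.  Loci with
    undefined theta get NaN.
    """
    theta = np.asarray(theta, dtype=float)
    p = np.full(theta.shape, np.nan)
    for b, vals in enumerate(null.null_values):
        sel = (null.bin_of_locus == b) & ~np.isnan(theta)
        if not sel.any() or len(vals) == 0:
            continue
        m = len(vals)
        n_ge = m - np.searchsorted(vals, theta[sel], side="left")
        p[sel] = (n_ge + 1.0) / (m + 1.0)
    return p


def call_outliers(
    stats: pd.DataFrame,
    p_threshold: float = 0.01,
    fdr_levels: tuple = (0.10, 0.01),
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Flag outliers at a raw-p threshold, BH FDR levels, and Bonferroni.

    The Bonferroni family-wise level equals ``p_threshold`` so the
    flag sets are nested: Bonferroni ⊆ FDR 1% ⊆ FDR 10% ⊆ raw p.
    """
    out = stats.copy()
    p = out["p_perm"].to_numpy(dtype=float)
    ok = ~np.isnan(p)
    q = np.full(p.shape, np.nan)
    q[ok] = bh_fdr(p[ok])
    out["q_bh"] = q
    out["outlier"] = ok & (p < p_threshold)
    for level in fdr_levels:
        out[f"outlier_fdr{int(round(level * 100))}"] = ok & (q <= level)
    if bonferroni:
        m = int(ok.sum())
        out["outlier_bonferroni"] = ok & (p < p_threshold / max(m, 1))
    return out


def scan_concordance(set_a: set, set_b: set, universe: set) -> dict:
    """Overlap summary of two outlier sets over a shared locus universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("outlier sets must come from the same locus universe")
    inter = set_a & set_b
    union = set_a | set_b
    n, na, nb, k = len(universe), len(set_a), len(set_b), len(inter)
    enrich_p = float(sps.hypergeom.sf(k - 1, n, na, nb)) if k else 1.0
    return {
        "n_universe": n,
        "n_a": na,
        "n_b": nb,
        "n_overlap": k,
        "jaccard": k / len(union) if union else float("nan"),
        "expected_overlap": na * nb / n if n else float("nan"),
        "enrichment_p": enrich_p,
    }


def fst_density_compare(
    gm_focal: GenotypeMatrix,
    gm_external: GenotypeMatrix,
    mt_labels=None,
    outlier_ids: set = frozenset(),
) -> pd.DataFrame:
    """Per-locus F_ST vectors for the four density comparisons.

    Within-focal mt-group wF_ST on the outlier and non-outlier locus
    subsets, plus focal-south vs external and focal-north vs external
    population F_ST on the shared loci.  Loci absent from either
    dataset are dropped (logged).
    """
    gm_focal, labels = _known_mt(gm_focal, mt_labels)
    shared = pd.Index(gm_focal.loci["locus_id"]).intersection(
        pd.Index(gm_external.loci["locus_id"])
    )
    n_drop = (len(gm_focal.loci) - len(shared)) + (len(gm_external.loci) - len(shared))
    if n_drop:
        logger.warning("fst_density_compare: dropped %d unshared loci", n_drop)
    fi = gm_focal.take_loci(gm_focal.loci["locus_id"].isin(shared).to_numpy())
    li = fi.loci.set_index("locus_id").index
    ext = gm_external.take_loci(gm_external.loci["locus_id"].isin(shared).to_numpy())
    ext = ext.take_loci(ext.loci.set_index("locus_id").index.get_indexer(li))

    theta_within, _, _, _ = wc_theta(fi.dosages, labels)
    is_out = fi.loci["locus_id"].isin(set(outlier_ids)).to_numpy()

    rows = []
    ids = fi.loci["locus_id"].to_numpy()
    rows.append(("within_outlier", ids[is_out], theta_within[is_out]))
    rows.append(("within_nonoutlier", ids[~is_out], theta_within[~is_out]))
    for side in ("south", "north"):
        side_gm = fi.take_samples(labels == side)
        combined = np.vstack([side_gm.dosages, ext.dosages])
        grp = np.array(["focal"] * side_gm.n_individuals + ["external"] * ext.n_individuals)
        theta, _, _, _ = wc_theta(combined, grp)
        rows.append((f"{side}_vs_external", ids, theta))
    frames = [
        pd.DataFrame({"comparison": name, "locus_id": i, "fst": v})
        for name, i, v in rows
    ]
    return pd.concat(frames, ignore_index=True)
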