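"""Ancestry-fraction estimation and the four-way mito-nuclear classification.

Two routes to a per-individual southern-ancestry fraction:

* an unsupervised EM maximising the standard admixture binomial
  log-likelihood  sum_{i,l} [ g log(sum_k q_ik p_kl)
  + (2-g) log(sum_k q_ik (1-p_kl)) ]  over ancestry fractions Q and
  cluster allele frequencies P;
* a supervised polygenic score over the outlier SNP panel: the fraction
  of an individual's alleles that are "south-associated" (the allele at
  higher frequency among southern-mt carriers).

Model-order selection follows the Evanno ΔK rule with a K=1 guard, and
an independent cluster-number check runs BIC-penalised k-means on
principal components.  Individuals are classified into four
mito-nuclear groups by their mt-haplotype and whether they carry at
least 30% nuclear ancestry from the opposite cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-6

__all__ = [
    "AncestryResult",
    "em_admixture",
    "best_of_seeds",
    "align_clusters",
    "align_q_columns",
    "KSelection",
    "select_k",
    "supervised_mt_score",
    "classify_mito_nuclear",
    "cluster_bic",
]


@dataclass
class AncestryResult:
    Q: np.ndarray  # individuals x K, rows sum to 1
    P: np.ndarray  # K x loci cluster allele frequencies
    loglik: float
    K: int
    n_iter: int
    converged: bool
    seed: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))


def _admixture_loglik(g, typed, Q, P) -> float:
    f = np.clip(Q @ P, _EPS, 1.0 - _EPS)
    g0 = np.where(typed, g, 0.0)
    g2 = np.where(typed, 2.0 - g, 0.0)
    return float(np.sum(g0 * np.log(f) + g2 * np.log(1.0 - f)))


def em_admixture(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> AncestryResult:
    """EM for the admixture model from a seeded random start.

    Missing genotypes contribute nothing to either likelihood or
    updates; cluster frequencies are clamped to [1e-6, 1-1e-6].  The
    log-likelihood (binomial kernel, constants dropped) is
    non-decreasing across iterations; convergence is declared when the
    relative increase falls below ``tol`` (scaled by 1 + |loglik|, so
    the criterion is meaningful for likelihoods of any magnitude).
    Non-convergence returns the best iterate, flagged.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    rng = np.random.default_rng(seed)
    g = gm.dosages
    typed = ~np.isnan(g)
    g0 = np.where(typed, g, 0.0)
    g2 = np.where(typed, 2.0 - g, 0.0)
    two_L = 2.0 * typed.sum(axis=1, keepdims=True).astype(float)
    if (two_L == 0).any():
        raise ValueError("an individual has no typed loci")

    freqs = np.clip(
        np.nansum(g, axis=0) / np.maximum(2.0 * typed.sum(axis=0), 1.0), _EPS, 1 - _EPS
    )
    P = np.clip(freqs[None, :] + rng.uniform(-0.1, 0.1, size=(K, gm.n_loci)), _EPS, 1 - _EPS)
    Q = rng.dirichlet(np.ones(K), size=gm.n_individuals)

    path = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f = np.clip(Q @ P, _EPS, 1.0 - _EPS)
        r1 = g0 / f          # n x L, weight of "alt allele" responsibilities
        r0 = g2 / (1.0 - f)
        A = Q * (r1 @ P.T)                 # n x K, expected alt-allele counts
        B = Q * (r0 @ (1.0 - P).T)         # expected ref-allele counts
        num = P * (Q.T @ r1)               # K x L
        den = num + (1.0 - P) * (Q.T @ r0)
        P = np.clip(num / np.maximum(den, 1e-300), _EPS, 1.0 - _EPS)
        Q = (A + B) / two_L
        Q = np.clip(Q, 0.0, None)
        Q /= Q.sum(axis=1, keepdims=True)

        ll = _admixture_loglik(g0, typed, Q, P)
        path.append(ll)
        if ll - ll_prev < tol * (1.0 + abs(ll)) and np.isfinite(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    if not converged:
        logger.warning("em_admixture: no convergence after %d iterations", max_iter)
    return AncestryResult(
        Q=Q, P=P, loglik=float(ll_prev), K=K, n_iter=it, converged=converged,
        seed=seed, loglik_path=np.array(path),
    )


def best_of_seeds(gm: GenotypeMatrix, K: int, seeds, **kw) -> AncestryResult:
    """Run EM from several seeds, keep the highest-likelihood fit."""
    runs = [em_admixture(gm, K, seed=s, **kw) for s in seeds]
    return max(runs, key=lambda r: r.loglik)


def align_clusters(P_ref: np.ndarray, result: AncestryResult) -> AncestryResult:
    """Resolve label switching by greedy matching of cluster frequency rows."""
    K = result.K
    dist = np.linalg.norm(P_ref[:, None, :] - result.P[None, :, :], axis=2)
    perm = np.full(K, -1)
    used = set()
    for r in np.argsort(dist.min(axis=1)):
        order = np.argsort(dist[r])
        for c in order:
            if c not in used:
                perm[r] = c
                used.add(c)
                break
    return AncestryResult(
        Q=result.Q[:, perm], P=result.P[perm], loglik=result.loglik, K=K,
        n_iter=result.n_iter, converged=result.converged, seed=result.seed,
        loglik_path=result.loglik_path,
    )


def align_q_columns(Q: np.ndarray, reference_q: np.ndarray) -> np.ndarray:
    """For K=2: return the Q column best correlated with a reference fraction."""
    if Q.shape[1] == 1:
        return Q[:, 0]
    cors = [np.corrcoef(Q[:, k], reference_q)[0, 1] for k in range(Q.shape[1])]
    return Q[:, int(np.nanargmax(cors))]


# ---------------------------------------------------------------------
# model-order selection
# ---------------------------------------------------------------------

@dataclass
class KSelection:
    table: pd.DataFrame  # K, mean_loglik, sd_loglik, delta_k
    chosen_k: int
    rule: str


def select_k(runs: dict) -> KSelection:
    """Evanno ΔK with a K=1 guard.

    ``runs`` maps each K in a contiguous range to >= 3 log-likelihoods.
    ΔK(K) = mean |L(K+1) − 2 L(K) + L(K−1)| / SD(L(K)) over paired
    runs; the chosen K is argmax of the mean log-likelihood if that is
    1 (ΔK cannot resolve K=1), otherwise argmax ΔK, ties broken toward
    smaller K.  Zero run-SD leaves ΔK undefined (NaN) at that K.
    """
    ks = sorted(runs)
    if any(len(runs[k]) < 3 for k in ks):
        raise ValueError("need >= 3 runs per K")
    if len(ks) >= 3 and ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    mean_l = {k: float(np.mean(runs[k])) for k in ks}
    sd_l = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    delta = {}
    for k in ks[1:-1]:
        n_runs = min(len(runs[k - 1]), len(runs[k]), len(runs[k + 1]))
        second = [
            abs(runs[k + 1][j] - 2.0 * runs[k][j] + runs[k - 1][j])
            for j in range(n_runs)
        ]
        delta[k] = float(np.mean(second) / sd_l[k]) if sd_l[k] > 0 else float("nan")
        if sd_l[k] == 0:
            logger.warning("select_k: zero SD at K=%d, delta-K undefined", k)
    best_ll = min(k for k in ks if mean_l[k] == max(mean_l.values()))
    if best_ll == 1 or not delta or all(np.isnan(v) for v in delta.values()):
        chosen, rule = best_ll, "max-mean-loglik (K=1 guard)"
    else:
        dmax = np.nanmax(list(delta.values()))
        chosen = min(k for k, v in delta.items() if v == dmax)
        rule = "delta-K"
    table = pd.DataFrame(
        {
            "K": ks,
            "mean_loglik": [mean_l[k] for k in ks],
            "sd_loglik": [sd_l[k] for k in ks],
            "delta_k": [delta.get(k, float("nan")) for k in ks],
        }
    )
    return KSelection(table=table, chosen_k=chosen, rule=rule)


# ---------------------------------------------------------------------
# supervised score and classification
# ---------------------------------------------------------------------

def supervised_mt_score(gm: GenotypeMatrix, mt_labels=None) -> pd.DataFrame:
    """Polygenic southern-ancestry score over an outlier SNP panel.

    Per locus the south-associated allele is the one at higher
    frequency among south-mt individuals; the score is the fraction of
    an individual's typed panel alleles that are south-associated.
    Loci with exactly equal group frequencies are dropped (logged).
    The orientation is re-derived from the data, so the score is
    invariant to ref/alt label flips.
    """
    labels = np.asarray(mt_labels if mt_labels is not None else gm.mt_labels())
    d = gm.dosages
    typed = ~np.isnan(d)
    south = labels == "south"
    north = labels == "north"
    if not south.any() or not north.any():
        raise ValueError("both mt-haplotype groups must be represented")

    def freq(mask):
        n = typed[mask].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, np.nansum(d[mask], axis=0) / (2.0 * n), np.nan)

    p_s, p_n = freq(south), freq(north)
    tie = p_s == p_n
    usable = ~tie & ~np.isnan(p_s) & ~np.isnan(p_n)
    if tie.any():
        logger.warning("supervised_mt_score: dropped %d tied loci", int(tie.sum()))
    if not usable.any():
        raise ValueError("no informative loci for the supervised score")
    south_is_alt = p_s > p_n
    south_dosage = np.where(south_is_alt[None, :], d, 2.0 - d)[:, usable]
    typed_u = typed[:, usable]
    n_typed = typed_u.sum(axis=1)
    score = np.nansum(np.where(typed_u, south_dosage, 0.0), axis=1) / np.maximum(
        2.0 * n_typed, 1.0
    )
    score = np.where(n_typed > 0, score, np.nan)
    return pd.DataFrame({"sample_id": gm.samples["sample_id"], "q_south": score})


FOUR_GROUPS = (
    "NorthMito-NorthNuc",
    "NorthMito-Mixed",
    "SouthMito-Mixed",
    "SouthMito-SouthNuc",
)


def classify_mito_nuclear(
    q_south: np.ndarray,
    mt_labels: np.ndarray,
    sample_ids=None,
    mixed_threshold: float = 0.30,
) -> pd.DataFrame:
    """Four-way mito-nuclear group per individual.

    North-mt individuals carrying >= ``mixed_threshold`` southern
    nuclear ancestry are "mixed" (boundary inclusive: at least 30% of
    alleles from the opposite cluster), and symmetrically for south-mt.
    Unknown mt labels are left unassigned.
    """
    q_south = np.asarray(q_south, dtype=float)
    mt = np.asarray(mt_labels)
    if np.nanmin(q_south) < 0 or np.nanmax(q_south) > 1:
        raise ValueError("q_south must lie in [0, 1]")
    groups = np.full(len(q_south), None, dtype=object)
    for i, (qi, m) in enumerate(zip(q_south, mt)):
        if np.isnan(qi) or m not in ("north", "south"):
            continue
        if m == "north":
            groups[i] = "NorthMito-Mixed" if qi >= mixed_threshold else "NorthMito-NorthNuc"
        else:
            groups[i] = (
                "SouthMito-Mixed" if (1.0 - qi) >= mixed_threshold else "SouthMito-SouthNuc"
            )
    if sample_ids is None:
        sample_ids = np.arange(len(q_south))
    return pd.DataFrame(
        {"sample_id": sample_ids, "mt_haplotype": mt, "q_south": q_south, "group": groups}
    )


# ---------------------------------------------------------------------
# cluster-number BIC
# ---------------------------------------------------------------------

def cluster_bic(
    gm: GenotypeMatrix,
    max_k: int = 5,
    n_pcs: int = 10,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """BIC-penalised k-means on principal components of the dosage matrix.

    Dosages are mean-imputed, centred and scaled before PCA; for each
    K, k-means runs with multiple restarts and the solution is scored
    as a hard-assignment spherical Gaussian mixture:
    BIC = −2·loglik + p·log(n) with p = (K−1) + K·d + 1 free
    parameters (mixing weights, cluster centres, one shared variance
    σ̂² = WSS/(d·(n−K))).  Penalties that act only on K (not on the
    K·d centre parameters) reward splitting spherical noise clusters
    — splitting one cluster in d dimensions cuts its WSS by ≈ 2/(πd)
    regardless of structure — so the full parameter count is needed
    for the curve to turn.  Returns the per-K curve and the argmin K.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    d = gm.dosages.copy()
    mu = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = np.take(mu, idx[1])
    sd = d.std(axis=0)
    keep = sd > 0
    z = (d[:, keep] - d[:, keep].mean(axis=0)) / d[:, keep].std(axis=0)
    n = z.shape[0]
    n_pcs = min(n_pcs, min(z.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(z)
    dim = pcs.shape[1]

    n_distinct = len(np.unique(pcs.round(12), axis=0))
    rows = []
    for k in range(1, max_k + 1):
        if k > n_distinct or k >= n:
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(pcs)
        wss = float(km.inertia_)
        sizes = np.bincount(km.labels_, minlength=k).astype(float)
        sigma2 = max(wss / (dim * (n - k)), 1e-12)
        loglik = (
            float(np.sum(sizes[sizes > 0] * np.log(sizes[sizes > 0] / n)))
            - 0.5 * n * dim * np.log(2.0 * np.pi * sigma2)
            - 0.5 * dim * (n - k)
        )
        n_params = (k - 1) + k * dim + 1
        bic = -2.0 * loglik + n_params * np.log(n)
        rows.append((k, wss, bic))
    table = pd.DataFrame(rows, columns=["K", "wss", "bic"])
    best_k = int(table.loc[table["bic"].idxmin(), "K"])
    return table, best_k
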