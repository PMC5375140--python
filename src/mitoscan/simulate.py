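"""Synthetic cohorts with mito-nuclear structure.

The generator emulates a single estuarine population segregating for
two divergent mitochondrial haplotypes ("north" / "south") genotyped by
GBS at ~11.7k sparse biallelic SNPs on ~10k genome scaffolds.  Most
loci carry only a small between-mt-group allele-frequency difference
(background δ ≈ 0.033); a planted subset (~349 loci) carries a larger
difference (δ ≈ 0.112) that is mediated by an individual-level
southern-ancestry fraction ``q`` — so the planted loci, and only they,
share a common two-cluster structure with a minority of mixed-ancestry
individuals.  A respiration phenotype is generated on top of ``q``
with covariates (body mass, acclimation and assay temperature) and a
slope calibrated to a target variance-explained.

All randomness flows from a single ``numpy.random.default_rng(seed)``
per operation, so outputs are bit-reproducible for a fixed scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, SimTruth

__all__ = [
    "SimScenario",
    "simulate_genotypes",
    "simulate_three_populations",
    "simulate_phenotype",
]

_MAX_RESAMPLE = 1000


@dataclass
class SimScenario:
    """Parameters of a simulated cohort.

    Defaults reproduce the study conditions: 155 individuals at a 60/40
    south/north mt-haplotype ratio, 11,705 SNPs on 10,180 scaffolds,
    349 planted loci with mean between-mt-group |Δp| = 0.112 against a
    background of 0.033, a truncated-Beta minor-allele-frequency family
    with mean ≈ 0.15 (giving He ≈ 0.2), and a phenotype whose
    southern-ancestry component explains 6% of the variance.
    """

    n_individuals: int = 155
    n_loci: int = 11705
    n_planted: int = 349
    mt_south_fraction: float = 0.60
    background_delta: float = 0.033
    planted_delta: float = 0.112
    delta_sd_frac: float = 0.30  # sd of per-locus delta, as a fraction of its mean
    miaf_beta_a: float = 1.5
    miaf_beta_b: float = 8.5
    miaf_lo: float = 0.01
    miaf_hi: float = 0.50
    missing_rate: float = 0.08
    n_scaffolds: int = 10180
    mixed_fraction: float = 21.0 / 155.0  # minority of mixed-ancestry individuals
    phenotype_effect: float = 0.06
    covariate_effects: dict = field(
        default_factory=lambda: {"mass": 0.20, "acclim": 0.05, "assay": 0.08}
    )
    phenotype_intercept: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mt_south_fraction", "missing_rate", "mixed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_planted > self.n_loci:
            raise ValueError("n_planted cannot exceed n_loci")
        if not self.planted_delta >= self.background_delta >= 0.0:
            raise ValueError("need planted_delta >= background_delta >= 0")
        if self.phenotype_effect >= 1.0 or self.phenotype_effect < 0.0:
            raise ValueError("phenotype_effect must lie in [0, 1)")
        if self.noise_sd <= 0.0:
            raise ValueError("noise_sd must be positive")


# ---------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------

def _draw_base_freqs(rng: np.random.Generator, sc: SimScenario, size: int) -> np.ndarray:
    """Baseline minor-allele frequencies: Beta(a, b) truncated to [lo, hi]."""
    out = np.empty(size)
    filled = 0
    for _ in range(_MAX_RESAMPLE):
        need = size - filled
        if need == 0:
            break
        draw = rng.beta(sc.miaf_beta_a, sc.miaf_beta_b, size=2 * need)
        ok = draw[(draw >= sc.miaf_lo) & (draw <= sc.miaf_hi)][:need]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    if filled < size:
        raise ValueError("could not sample the requested MiAF family")
    return out


def _draw_deltas(
    rng: np.random.Generator, mean: float, sd_frac: float, size: int
) -> np.ndarray:
    """Per-locus |Δp|: normal around ``mean``, negatives resampled."""
    if mean == 0.0:
        return np.zeros(size)
    sd = sd_frac * mean
    out = rng.normal(mean, sd, size=size)
    for _ in range(_MAX_RESAMPLE):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise ValueError("could not sample positive deltas")


def _split_freqs(
    rng: np.random.Generator, base: np.ndarray, delta: np.ndarray, sc: SimScenario
) -> tuple[np.ndarray, np.ndarray]:
    """Two group frequencies ±δ/2 around the base, random direction per locus.

    Loci whose split would leave (0, 1) are resampled (base frequency
    and direction); an infeasible delta raises.
    """
    size = len(base)
    sign = rng.choice([-1.0, 1.0], size=size)
    lo_f, hi_f = base - delta / 2.0 * sign, base + delta / 2.0 * sign
    for _ in range(_MAX_RESAMPLE):
        bad = (np.minimum(lo_f, hi_f) <= 0.0) | (np.maximum(lo_f, hi_f) >= 1.0)
        if not bad.any():
            return lo_f, hi_f
        nb = int(bad.sum())
        base_new = _draw_base_freqs(rng, sc, nb)
        sign_new = rng.choice([-1.0, 1.0], size=nb)
        lo_f[bad] = base_new - delta[bad] / 2.0 * sign_new
        hi_f[bad] = base_new + delta[bad] / 2.0 * sign_new
    raise ValueError(
        "scenario infeasible: delta too large for the configured MiAF family"
    )


def _locus_coordinates(
    rng: np.random.Generator, n_loci: int, n_scaffolds: int
) -> pd.DataFrame:
    """Assign loci to scaffolds with mostly >1kb gaps, a minority within 64bp tags."""
    counts = rng.multinomial(n_loci, np.full(n_scaffolds, 1.0 / n_scaffolds))
    rows = []
    lid = 0
    width = len(str(n_scaffolds))
    for s, cnt in enumerate(counts):
        if cnt == 0:
            continue
        name = f"scaffold_{s:0{width}d}"
        pos = int(rng.integers(100, 100_000))
        for _ in range(cnt):
            rows.append((f"snp_{lid:06d}", name, pos))
            lid += 1
            if rng.random() < 0.10:  # same 64bp sequencing tag
                pos += int(rng.integers(10, 64))
            else:
                pos += int(rng.integers(5_000, 500_000))
    return pd.DataFrame(rows, columns=["locus_id", "scaffold", "pos"])


def _true_ancestry(
    rng: np.random.Generator, mt: np.ndarray, sc: SimScenario
) -> np.ndarray:
    """Per-individual southern-ancestry fraction.

    Pure individuals sit near 0 (north mt) or 1 (south mt); a minority
    (``mixed_fraction``) draws uniformly from (0.3, 0.7).
    """
    n = len(mt)
    q = np.empty(n)
    mixed = rng.random(n) < sc.mixed_fraction
    south = mt == "south"
    q[south & ~mixed] = rng.beta(30, 2, size=int((south & ~mixed).sum()))
    q[~south & ~mixed] = rng.beta(2, 30, size=int((~south & ~mixed).sum()))
    q[mixed] = rng.uniform(0.3, 0.7, size=int(mixed.sum()))
    return q


def _four_way_group(q: np.ndarray, mt: np.ndarray, threshold: float = 0.30) -> np.ndarray:
    out = np.empty(len(q), dtype=object)
    for i, (qi, m) in enumerate(zip(q, mt)):
        if m == "north":
            out[i] = "NorthMito-Mixed" if qi >= threshold else "NorthMito-NorthNuc"
        else:
            out[i] = "SouthMito-Mixed" if (1.0 - qi) >= threshold else "SouthMito-SouthNuc"
    return out


# ---------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------

def simulate_genotypes(scenario: SimScenario) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate the single-population cohort with planted mito-nuclear loci.

    Every between-mt-group frequency difference is mediated by the
    individual-level southern-ancestry fraction ``q`` — in a panmictic
    population a genuine mt-group difference can only be carried by
    individuals, so both background loci (small per-locus δ around
    ``background_delta``) and planted loci (δ around ``planted_delta``)
    get two ancestry-cluster frequencies separated by δ/(q̄_S − q̄_N),
    which makes the realized *between-mt-group* difference centre on
    the configured δ.  Genotypes are binomial in the individual's
    ancestry-mixed frequency; only the planted subset is separated
    strongly enough to matter downstream, and it is what creates the
    shared two-cluster structure with mixed-ancestry individuals.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n, L = sc.n_individuals, sc.n_loci

    n_south = int(round(sc.mt_south_fraction * n))
    mt = np.array(["north"] * n, dtype=object)
    mt[rng.permutation(n)[:n_south]] = "south"

    q = _true_ancestry(rng, mt, sc)
    planted_idx = np.sort(rng.choice(L, size=sc.n_planted, replace=False))
    is_planted = np.zeros(L, dtype=bool)
    is_planted[planted_idx] = True

    base = _draw_base_freqs(rng, sc, L)
    south = mt == "south"
    gap = float(q[south].mean() - q[~south].mean()) if south.any() and (~south).any() else 1.0
    if gap <= 0.05:
        raise ValueError(
            "scenario infeasible: mt groups do not separate in true ancestry"
        )
    delta = np.empty(L)
    delta[~is_planted] = _draw_deltas(
        rng, sc.background_delta, sc.delta_sd_frac, L - sc.n_planted
    )
    delta[is_planted] = _draw_deltas(rng, sc.planted_delta, sc.delta_sd_frac, sc.n_planted)
    pN, pS = _split_freqs(rng, base, delta / gap, sc)
    probs = q[:, None] * pS[None, :] + (1.0 - q[:, None]) * pN[None, :]

    dosages = rng.binomial(2, probs).astype(float)
    if sc.missing_rate > 0:
        dosages[rng.random((n, L)) < sc.missing_rate] = np.nan

    coords = _locus_coordinates(rng, L, sc.n_scaffolds)
    coords["ref"] = "A"
    coords["alt"] = "G"
    samples = pd.DataFrame(
        {
            "sample_id": [f"MK_{i:04d}" for i in range(n)],
            "mt_haplotype": mt,
            "population": "MK",
        }
    )
    gm = GenotypeMatrix(dosages=dosages, loci=coords[["locus_id", "scaffold", "pos", "ref", "alt"]], samples=samples)
    truth = SimTruth(
        planted_locus_ids=set(coords["locus_id"].to_numpy()[planted_idx]),
        true_q=q,
        true_group=_four_way_group(q, mt),
    )
    return gm, truth


def simulate_three_populations(
    scenario: SimScenario,
    divergence: float = 0.05,
    pop_sizes: dict | None = None,
) -> GenotypeMatrix:
    """Three diverged populations (Balding–Nichols draws).

    Every population's allele frequency at a locus is an independent
    Beta draw around the shared ancestral frequency with drift
    parameter F = ``divergence`` (variance F·p(1−p)), so each forms its
    own cluster; the focal (first-listed) population contains both
    mt-haplotypes at the configured ratio.
    """
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    sizes = pop_sizes or {"MK": scenario.n_individuals, "ME": 35, "GA": 38}
    if len(sizes) < 3 or any(v <= 0 for v in sizes.values()):
        raise ValueError("need >= 3 populations with positive sizes")
    rng = np.random.default_rng(scenario.seed)
    L = scenario.n_loci
    anc = _draw_base_freqs(rng, scenario, L)

    pop_names = list(sizes)
    focal = pop_names[0]
    freqs = {}
    for name in pop_names:
        if divergence == 0.0:
            freqs[name] = anc.copy()
        else:
            f = divergence
            a = anc * (1.0 - f) / f
            b = (1.0 - anc) * (1.0 - f) / f
            freqs[name] = np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)

    rows_d, mt_all, pop_all, ids = [], [], [], []
    for name in pop_names:
        n_pop = sizes[name]
        rows_d.append(rng.binomial(2, np.broadcast_to(freqs[name], (n_pop, L))).astype(float))
        if name == focal:
            n_south = int(round(scenario.mt_south_fraction * n_pop))
            mt = np.array(["north"] * n_pop, dtype=object)
            mt[rng.permutation(n_pop)[:n_south]] = "south"
        else:
            mt = np.array(["unknown"] * n_pop, dtype=object)
        mt_all.append(mt)
        pop_all.extend([name] * n_pop)
        ids.extend([f"{name}_{i:04d}" for i in range(n_pop)])

    dosages = np.vstack(rows_d)
    if scenario.missing_rate > 0:
        dosages[rng.random(dosages.shape) < scenario.missing_rate] = np.nan
    coords = _locus_coordinates(rng, L, scenario.n_scaffolds)
    coords["ref"] = "A"
    coords["alt"] = "G"
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "mt_haplotype": np.concatenate(mt_all),
            "population": pop_all,
        }
    )
    return GenotypeMatrix(
        dosages=dosages,
        loci=coords[["locus_id", "scaffold", "pos", "ref", "alt"]],
        samples=samples,
    )


# ---------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------

def ancestry_slope(
    phenotype_effect: float, noise_sd: float, q: np.ndarray, n_covariate_params: int = 6
) -> float:
    """Slope on true ancestry giving the target *expected sample R²*.

    Calibrated for the partial-regression path: both phenotype and
    ancestry are residualized on a p-parameter covariate design (p =
    ``n_covariate_params``: intercept, mass, acclimation, two assay
    contrasts, admixture) before the final one-predictor OLS.
    Residualization shrinks the ancestry sum of squares by
    κ = (n−p)/(n−1) in expectation, and the sample R² of the final
    step is upward-biased (E[R²] ≈ (λ+1)/(λ+n−p) with noncentrality
    λ = β²·κ·S_qq/σ²), so the slope solves E[R²] = phenotype_effect
    under that relation rather than setting the population
    ρ² = phenotype_effect.
    """
    e = phenotype_effect
    if e == 0.0:
        return 0.0
    n = len(q)
    p = n_covariate_params
    kappa = (n - p) / (n - 1.0)
    lam = max((e * (n - p) - 1.0) / (1.0 - e), 0.0)
    s_qq = float(np.sum((q - q.mean()) ** 2))
    if s_qq == 0:
        raise ValueError("true ancestry has no variance; cannot calibrate slope")
    return float(np.sqrt(lam * noise_sd**2 / (kappa * s_qq)))


def simulate_phenotype(
    truth: SimTruth, scenario: SimScenario, sample_ids=None, seed_offset: int = 1
) -> pd.DataFrame:
    """State-3 respiration rates with covariates on top of true ancestry.

    phenotype = intercept + covariates + slope·q + N(0, noise_sd²); the
    slope is calibrated so the expected R² of covariate-residualized
    phenotype on ``q`` equals ``phenotype_effect``.  Covariates: body
    mass log-normal (median 8 g), acclimation temperature uniform over
    {12, 28} °C, assay temperature uniform over {12, 20, 28} °C.
    """
    sc = scenario
    if truth.true_q is None:
        raise ValueError("truth lacks true ancestry")
    q = np.asarray(truth.true_q, dtype=float)
    n = len(q)
    rng = np.random.default_rng(sc.seed + seed_offset)

    mass = rng.lognormal(mean=np.log(8.0), sigma=0.25, size=n)
    acclim = rng.choice([12.0, 28.0], size=n)
    assay = rng.choice([12.0, 20.0, 28.0], size=n)
    admix = np.clip(rng.normal(0.032, 0.02, size=n), 0.0, 0.147)

    beta_q = ancestry_slope(sc.phenotype_effect, sc.noise_sd, q)
    ce = sc.covariate_effects
    y = (
        sc.phenotype_intercept
        + ce.get("mass", 0.0) * mass
        + ce.get("acclim", 0.0) * acclim
        + ce.get("assay", 0.0) * assay
        + beta_q * q
        + rng.normal(0.0, sc.noise_sd, size=n)
    )
    truth.phenotype_coefficients = {
        "intercept": sc.phenotype_intercept,
        "mass": ce.get("mass", 0.0),
        "acclim": ce.get("acclim", 0.0),
        "assay": ce.get("assay", 0.0),
        "ancestry_slope": beta_q,
    }
    if sample_ids is None:
        sample_ids = [f"MK_{i:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "state3_rate": y,
            "mass_g": mass,
            "acclim_C": acclim,
            "assay_C": assay,
            "admix": admix,
        }
    )
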