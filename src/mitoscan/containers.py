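"""Core in-memory containers shared by every pipeline stage.

The substrate of the whole analysis is a diploid dosage matrix
(individuals x loci, entries 0/1/2 counting alternate alleles, NaN for
missing calls) together with ordered locus coordinates and sample
metadata.  Loci live on genome scaffolds; samples carry a mitochondrial
haplotype label (``north`` / ``south`` / ``unknown``) and a population
label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MT_LABELS = ("north", "south", "unknown")

LOCUS_COLUMNS = ["locus_id", "scaffold", "pos", "ref", "alt"]
SAMPLE_COLUMNS = ["sample_id", "mt_haplotype", "population"]


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid dosage matrix with coordinates and metadata.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_individuals, n_loci)`` with entries in
        ``{0, 1, 2}`` counting copies of the alternate allele, ``NaN``
        marking missing genotypes.
    loci
        One row per locus: ``locus_id`` (unique string), ``scaffold``,
        ``pos`` (1-based, strictly increasing within a scaffold),
        ``ref``, ``alt`` (single bases).
    samples
        One row per individual: ``sample_id`` (unique), ``mt_haplotype``
        in ``{north, south, unknown}``, ``population``.
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x loci array")
        n_ind, n_loc = self.dosages.shape
        if len(self.samples) != n_ind:
            raise ValueError(
                f"samples table has {len(self.samples)} rows for {n_ind} individuals"
            )
        if len(self.loci) != n_loc:
            raise ValueError(f"loci table has {len(self.loci)} rows for {n_loc} loci")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")
        if self.loci["locus_id"].duplicated().any():
            raise ValueError("locus ids must be unique")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        bad_mt = set(self.samples["mt_haplotype"]) - set(MT_LABELS)
        if bad_mt:
            raise ValueError(f"unknown mt-haplotype labels: {sorted(bad_mt)}")
        for _, grp in self.loci.groupby("scaffold", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within a scaffold")
        self.loci = self.loci.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- shape ----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    # -- subsetting -----------------------------------------------------
    def take_loci(self, index) -> "GenotypeMatrix":
        """Return a copy restricted to the given locus indices (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index].copy(),
            loci=self.loci.iloc[index].reset_index(drop=True),
            samples=self.samples.copy(),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :].copy(),
            loci=self.loci.copy(),
            samples=self.samples.iloc[index].reset_index(drop=True),
        )

    def mt_labels(self) -> np.ndarray:
        return self.samples["mt_haplotype"].to_numpy()


@dataclass
class SimTruth:
    """Ground truth attached to a simulated cohort."""

    planted_locus_ids: set = field(default_factory=set)
    true_q: np.ndarray | None = None  # per-individual southern-ancestry fraction
    true_group: np.ndarray | None = None  # four-way mito-nuclear label
    phenotype_coefficients: dict = field(default_factory=dict)


@dataclass
class FilterReport:
    """Accounting of a locus-filtering step.

    A locus is attributed to the first filter that removes it, in the
    order MAF -> call rate -> HWE -> thinning.
    """

    n_input_loci: int = 0
    n_removed_maf: int = 0
    n_removed_callrate: int = 0
    n_removed_hwe: int = 0
    n_removed_thin: int = 0
    removed_maf: list = field(default_factory=list)
    removed_callrate: list = field(default_factory=list)
    removed_hwe: list = field(default_factory=list)
    removed_thin: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return (
            self.n_input_loci
            - self.n_removed_maf
            - self.n_removed_callrate
            - self.n_removed_hwe
            - self.n_removed_thin
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for which, ids in [
            ("maf", self.removed_maf),
            ("call_rate", self.removed_callrate),
            ("hwe_excess_het", self.removed_hwe),
            ("thin", self.removed_thin),
        ]:
            rows.extend({"locus_id": lid, "removed_by": which} for lid in ids)
        return pd.DataFrame(rows, columns=["locus_id", "removed_by"])
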