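"""Genotype/metadata I/O and the locus QC filters.

VCF is the on-disk genotype format (read through pysam, written as
plain VCFv4.2 text with GT-only FORMAT fields); sample metadata and
phenotypes travel as TSV.  The QC chain mirrors standard GBS practice:
minor-allele-frequency floor, per-locus call-rate floor, exclusion of
heterozygote-excess loci (paralog collapse signature), and optional
physical-distance thinning.  Filter order is fixed as
MAF -> call rate -> HWE -> thinning, and a locus is attributed to the
first filter that removes it.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import SAMPLE_COLUMNS, FilterReport, GenotypeMatrix
from .popgen import locus_summaries

logger = logging.getLogger(__name__)

METADATA_COLUMNS = [
    "sample_id",
    "mt_haplotype",
    "population",
    "mass_g",
    "acclim_C",
    "assay_C",
    "state3_rate",
]


# ---------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 file with GT genotypes (0/0, 0/1, 1/1, ./.)."""
    path = Path(path)
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mitoscan\n")
        for sc in pd.unique(gm.loci["scaffold"]):
            fh.write(f"##contig=<ID={sc}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples["sample_id"])
            + "\n"
        )
        for j, locus in gm.loci.iterrows():
            gts = [
                gt_code.get(g, "./.") if not np.isnan(g) else "./."
                for g in gm.dosages[:, j]
            ]
            fh.write(
                f"{locus.scaffold}\t{locus.pos}\t{locus.locus_id}\t"
                f"{locus.ref}\t{locus.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path, metadata: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a `GenotypeMatrix`.

    Multiallelic or non-SNP records are skipped with a logged count.
    Missing genotypes (``./.`` or half calls) become NaN.  If a sample
    metadata frame (``sample_id``, ``mt_haplotype``, ``population``) is
    given it is joined by sample id; otherwise labels default to
    ``unknown``.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:  # malformed header
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vf.header.samples)
    rows = []
    dosage_rows = []
    n_skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped += 1
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            n_skipped += 1
            continue
        gt_row = np.full(len(sample_ids), np.nan)
        for i, sid in enumerate(sample_ids):
            alleles = rec.samples[sid]["GT"]
            if alleles is None or any(a is None for a in alleles):
                continue
            gt_row[i] = float(sum(alleles))
        rows.append(
            (
                rec.id if rec.id else f"{rec.chrom}:{rec.pos}",
                rec.chrom,
                rec.pos,
                rec.ref,
                rec.alts[0],
            )
        )
        dosage_rows.append(gt_row)
    vf.close()
    if n_skipped:
        logger.warning("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    loci = pd.DataFrame(rows, columns=["locus_id", "scaffold", "pos", "ref", "alt"])
    dosages = (
        np.asarray(dosage_rows).T if dosage_rows else np.empty((len(sample_ids), 0))
    )
    samples = pd.DataFrame({"sample_id": sample_ids})
    if metadata is not None:
        samples = samples.merge(metadata, on="sample_id", how="left")
    samples["mt_haplotype"] = samples.get(
        "mt_haplotype", pd.Series(["unknown"] * len(samples))
    ).fillna("unknown")
    samples["population"] = samples.get(
        "population", pd.Series(["NA"] * len(samples))
    ).fillna("NA")
    return GenotypeMatrix(dosages=dosages, loci=loci, samples=samples[
        [c for c in samples.columns if c in set(SAMPLE_COLUMNS) | set(METADATA_COLUMNS)]
    ])


def write_metadata(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------

def filter_loci(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.70,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop loci with MiAF < ``maf_min`` or call rate < ``call_rate_min``.

    Both boundaries are inclusive on the keep side (a locus at exactly
    the threshold is retained).  MiAF is computed over non-missing
    calls only.
    """
    for thr in (maf_min, call_rate_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("filter thresholds must lie in [0, 1]")
    summ = locus_summaries(gm)
    miaf = summ["miaf"].to_numpy()
    cr = summ["call_rate"].to_numpy()
    fail_maf = ~(miaf >= maf_min)  # NaN (all-missing) fails too
    fail_cr = (cr < call_rate_min) & ~fail_maf
    keep = ~fail_maf & ~fail_cr
    ids = gm.loci["locus_id"].to_numpy()
    report = FilterReport(
        n_input_loci=gm.n_loci,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_callrate=int(fail_cr.sum()),
        removed_maf=list(ids[fail_maf]),
        removed_callrate=list(ids[fail_cr]),
    )
    return gm.take_loci(keep), report


def hwe_excess_het_pvalue(n_het: int, n_hom_alt: int, n_hom_ref: int) -> float:
    """One-sided exact p for heterozygote *excess* at a biallelic locus.

    Conditional on the observed allele counts, the number of
    heterozygotes under Hardy–Weinberg follows the Levene–Haldane
    distribution; the p-value sums its probabilities over heterozygote
    counts >= the observed one (same parity as the minor-allele count).
    """
    n = n_het + n_hom_alt + n_hom_ref
    n_alt = n_het + 2 * n_hom_alt
    n_ref = n_het + 2 * n_hom_ref
    n_minor = min(n_alt, n_ref)
    if n == 0 or n_minor == 0:
        return 1.0
    lg = math.lgamma
    log_const = lg(n + 1) + lg(n_alt + 1) + lg(n_ref + 1) - lg(2 * n + 1)

    def log_prob(h: int) -> float:
        return (
            log_const
            + h * math.log(2.0)
            - lg(h + 1)
            - lg((n_alt - h) // 2 + 1)
            - lg((n_ref - h) // 2 + 1)
        )

    hs = range(n_minor % 2, n_minor + 1, 2)
    total = 0.0
    tail = 0.0
    for h in hs:
        pr = math.exp(log_prob(h))
        total += pr
        if h >= n_het:
            tail += pr
    return min(tail / total, 1.0)


def hwe_excess_het_filter(
    gm: GenotypeMatrix, alpha: float = 0.01
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci with Ho > He and a significant exact excess-het test.

    Loci with fewer than two typed individuals are retained (flagged in
    the log); loci with Ho <= He are retained regardless of p.
    """
    d = gm.dosages
    typed = ~np.isnan(d)
    n_typed = typed.sum(axis=0)
    summ = locus_summaries(gm)
    remove = np.zeros(gm.n_loci, dtype=bool)
    for j in range(gm.n_loci):
        if n_typed[j] < 2:
            logger.warning(
                "hwe filter: locus %s has <2 typed individuals, retained",
                gm.loci["locus_id"].iloc[j],
            )
            continue
        if not summ["ho"].iloc[j] > summ["he"].iloc[j]:
            continue
        col = d[typed[:, j], j]
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 2).sum())
        n_hom_ref = int((col == 0).sum())
        if hwe_excess_het_pvalue(n_het, n_hom_alt, n_hom_ref) < alpha:
            remove[j] = True
    ids = gm.loci["locus_id"].to_numpy()
    report = FilterReport(
        n_input_loci=gm.n_loci,
        n_removed_hwe=int(remove.sum()),
        removed_hwe=list(ids[remove]),
    )
    return gm.take_loci(~remove), report


def thin_by_distance(
    gm: GenotypeMatrix, min_bp: int = 100
) -> tuple[GenotypeMatrix, FilterReport]:
    """Greedy left-to-right thinning within each scaffold.

    Keep the first locus; drop any locus <= ``min_bp`` from the last
    kept one.  Retained loci are pairwise > ``min_bp`` apart within a
    scaffold; single-locus scaffolds are always retained.
    """
    keep = np.zeros(gm.n_loci, dtype=bool)
    scaff = gm.loci["scaffold"].to_numpy()
    pos = gm.loci["pos"].to_numpy()
    last_kept: dict = {}
    for j in range(gm.n_loci):
        sc = scaff[j]
        if sc not in last_kept or pos[j] - last_kept[sc] > min_bp:
            keep[j] = True
            last_kept[sc] = pos[j]
    ids = gm.loci["locus_id"].to_numpy()
    report = FilterReport(
        n_input_loci=gm.n_loci,
        n_removed_thin=int((~keep).sum()),
        removed_thin=list(ids[~keep]),
    )
    return gm.take_loci(keep), report


def filter_samples_by_call_rate(
    gm: GenotypeMatrix, min_rate: float = 0.50
) -> GenotypeMatrix:
    """Optional two-pass individual filter: drop samples typed at < ``min_rate`` of loci."""
    rate = (~np.isnan(gm.dosages)).mean(axis=1)
    return gm.take_samples(rate >= min_rate)


def apply_qc(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.70,
    hwe_alpha: float = 0.01,
    thin_bp: int | None = None,
    sample_call_rate: float | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """The full QC chain in fixed order: MAF -> call rate -> HWE -> thinning."""
    if sample_call_rate is not None:
        gm = filter_samples_by_call_rate(gm, sample_call_rate)
    out, rep1 = filter_loci(gm, maf_min=maf_min, call_rate_min=call_rate_min)
    out, rep2 = hwe_excess_het_filter(out, alpha=hwe_alpha)
    rep = FilterReport(
        n_input_loci=rep1.n_input_loci,
        n_removed_maf=rep1.n_removed_maf,
        n_removed_callrate=rep1.n_removed_callrate,
        n_removed_hwe=rep2.n_removed_hwe,
        removed_maf=rep1.removed_maf,
        removed_callrate=rep1.removed_callrate,
        removed_hwe=rep2.removed_hwe,
    )
    if thin_bp is not None:
        out, rep3 = thin_by_distance(out, min_bp=thin_bp)
        rep.n_removed_thin = rep3.n_removed_thin
        rep.removed_thin = rep3.removed_thin
    return out, rep
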