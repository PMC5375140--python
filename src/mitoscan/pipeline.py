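"""End-to-end pipeline: simulate/ingest -> QC -> scan -> ancestry -> phenotype.

A run is described by a flat key-value config (YAML on disk).  Every
stage persists its tables under the output directory and the run ends
with a manifest (config hash, per-file checksums, wall-clock per stage,
warnings) so any number in the final report traces to a file and
identical configs reproduce identical checksums for deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ancestry, gio, phenotype, scan, simulate
from .popgen import fisher_exact_allele, locus_summaries

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run."""

    out_dir: str = "results/run"
    # input: either a VCF + metadata, or a simulation scenario
    vcf: str | None = None
    metadata: str | None = None
    simulate: bool = True
    seed: int = 1
    n_individuals: int = 155
    n_loci: int = 11705
    n_planted: int = 349
    mt_south_fraction: float = 0.60
    background_delta: float = 0.033
    planted_delta: float = 0.112
    missing_rate: float = 0.08
    phenotype_effect: float = 0.06
    # QC
    maf_min: float = 0.01
    call_rate_min: float = 0.70
    hwe_alpha: float = 0.01
    thin_bp: int = 0  # 0 = no thinning
    # scan
    n_perm: int = 200
    he_bins: int = 10
    p_threshold: float = 0.01
    fdr_levels: tuple = (0.10, 0.01)
    # ancestry
    k: int = 2
    n_runs: int = 3
    mixed_threshold: float = 0.30
    ancestry_outlier_set: str = "raw"  # raw | fdr10 | fdr1
    # which ancestry fraction feeds the 30%-rule classification: the EM
    # (STRUCTURE-style) Q separates to 0/1, while the raw allele-sharing
    # score compresses toward 0.5 at small per-locus frequency differences
    classify_on: str = "em"  # em | supervised
    # phenotype
    run_assoc: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}, fh)

    def scenario(self) -> simulate.SimScenario:
        return simulate.SimScenario(
            n_individuals=self.n_individuals,
            n_loci=self.n_loci,
            n_planted=self.n_planted,
            mt_south_fraction=self.mt_south_fraction,
            background_delta=self.background_delta,
            planted_delta=self.planted_delta,
            missing_rate=self.missing_rate,
            phenotype_effect=self.phenotype_effect,
            seed=self.seed,
        )


@dataclass
class RunManifest:
    config_hash: str = ""
    version: str = ""
    stages: dict = field(default_factory=dict)  # stage -> {seconds, outputs: {path: sha256}}
    warnings: list = field(default_factory=list)
    error: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, persisting every intermediate table.

    A stage failure leaves prior stage outputs intact and is recorded
    in the manifest together with their checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        version=__version__,
    )

    if config.run_assoc and not config.simulate and config.metadata is None:
        raise ValueError("assoc stage enabled but no phenotype/metadata table given")

    def finish_stage(name: str, t0: float, outputs: list[Path]) -> None:
        manifest.stages[name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {str(p): _sha256(p) for p in outputs},
        }

    try:
        # ---- stage: input -------------------------------------------
        t0 = time.perf_counter()
        pheno = None
        truth = None
        if config.simulate:
            scenario = config.scenario()
            gm, truth = simulate.simulate_genotypes(scenario)
            pheno = simulate.simulate_phenotype(
                truth, scenario, sample_ids=gm.samples["sample_id"].tolist()
            )
            gio.write_vcf(gm, out / "genotypes.vcf")
            meta = gm.samples.merge(pheno, on="sample_id")
            gio.write_metadata(meta, out / "metadata.tsv")
            truth_tab = pd.DataFrame(
                {
                    "sample_id": gm.samples["sample_id"],
                    "true_q_south": truth.true_q,
                    "true_group": truth.true_group,
                }
            )
            truth_tab.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
            pd.DataFrame(
                {
                    "locus_id": gm.loci["locus_id"],
                    "planted": gm.loci["locus_id"].isin(truth.planted_locus_ids),
                }
            ).to_csv(out / "truth_loci.tsv", sep="\t", index=False)
            finish_stage(
                "simulate",
                t0,
                [out / p for p in ("genotypes.vcf", "metadata.tsv", "truth_samples.tsv", "truth_loci.tsv")],
            )
        else:
            meta = gio.read_metadata(config.metadata) if config.metadata else None
            gm = gio.read_vcf(config.vcf, metadata=meta)
            pheno = meta
            finish_stage("ingest", t0, [])

        # ---- stage: QC ----------------------------------------------
        t0 = time.perf_counter()
        gm_f, report = gio.apply_qc(
            gm,
            maf_min=config.maf_min,
            call_rate_min=config.call_rate_min,
            hwe_alpha=config.hwe_alpha,
            thin_bp=config.thin_bp or None,
        )
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        finish_stage("qc", t0, [out / "filter_report.tsv"])

        # ---- stage: scan --------------------------------------------
        t0 = time.perf_counter()
        stats = locus_summaries(gm_f)
        fst = scan.wfst_scan(gm_f)
        stats = stats.merge(fst, on="locus_id")
        null = scan.permutation_null(
            gm_f, n_perm=config.n_perm, he_bins=config.he_bins, seed=config.seed
        )
        stats["p_perm"] = scan.empirical_p(stats["fst"].to_numpy(), null)
        stats = scan.call_outliers(
            stats, p_threshold=config.p_threshold, fdr_levels=tuple(config.fdr_levels)
        )
        stats = stats.merge(fisher_exact_allele(gm_f, gm_f.mt_labels()), on="locus_id")
        stats.to_csv(out / "scan_results.tsv", sep="\t", index=False)
        np.savez_compressed(
            out / "permutation_null.npz",
            bin_edges=null.bin_edges,
            bin_of_locus=null.bin_of_locus,
            **{f"bin_{b}": v for b, v in enumerate(null.null_values)},
        )
        outlier_ids = set(stats.loc[stats["outlier"], "locus_id"])
        fisher_ids = set(stats.loc[stats["fisher_p"] < config.p_threshold, "locus_id"])
        concord = scan.scan_concordance(
            outlier_ids, fisher_ids, set(stats["locus_id"])
        )
        with open(out / "concordance.json", "w") as fh:
            json.dump(concord, fh, indent=2)
        finish_stage(
            "scan",
            t0,
            [out / p for p in ("scan_results.tsv", "permutation_null.npz", "concordance.json")],
        )

        # ---- stage: ancestry ----------------------------------------
        t0 = time.perf_counter()
        key = {"raw": "outlier", "fdr10": "outlier_fdr10", "fdr1": "outlier_fdr1"}[
            config.ancestry_outlier_set
        ]
        panel_ids = set(stats.loc[stats[key], "locus_id"])
        panel = gm_f.take_loci(gm_f.loci["locus_id"].isin(panel_ids).to_numpy())
        score = ancestry.supervised_mt_score(panel)
        em = ancestry.best_of_seeds(
            panel, config.k, seeds=range(config.seed, config.seed + config.n_runs)
        )
        q_em = ancestry.align_q_columns(em.Q, score.set_index("sample_id").loc[
            panel.samples["sample_id"], "q_south"
        ].to_numpy())
        score["q_south_em"] = q_em
        score.to_csv(out / "ancestry_q.tsv", sep="\t", index=False)
        q_for_groups = {"em": "q_south_em", "supervised": "q_south"}[config.classify_on]
        assign = ancestry.classify_mito_nuclear(
            score[q_for_groups].to_numpy(),
            panel.samples["mt_haplotype"].to_numpy(),
            sample_ids=panel.samples["sample_id"].to_numpy(),
            mixed_threshold=config.mixed_threshold,
        )
        assign.to_csv(out / "mito_nuclear_groups.tsv", sep="\t", index=False)
        finish_stage("ancestry", t0, [out / "ancestry_q.tsv", out / "mito_nuclear_groups.tsv"])

        # ---- stage: phenotype association ---------------------------
        if config.run_assoc and pheno is not None and "state3_rate" in pheno.columns:
            t0 = time.perf_counter()
            anc = phenotype.ancova_groups(pheno, assign)
            anc.anova.to_csv(out / "ancova_table.tsv", sep="\t")
            anc.tukey.to_csv(out / "tukey_table.tsv", sep="\t", index=False)
            reg = phenotype.regress_ancestry(
                pheno,
                score.set_index("sample_id")[q_for_groups].rename("q_south"),
            )
            pd.DataFrame(
                [
                    {
                        "slope": reg.slope,
                        "slope_se": reg.slope_se,
                        "r2": reg.r2,
                        "p_value": reg.p_value,
                        "n": reg.n_used,
                        "ancova_group_p": anc.p_value,
                    }
                ]
            ).to_csv(out / "assoc_summary.tsv", sep="\t", index=False)
            finish_stage(
                "assoc",
                t0,
                [out / p for p in ("ancova_table.tsv", "tukey_table.tsv", "assoc_summary.tsv")],
            )
    except Exception as exc:  # record failure, keep prior outputs
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.to_json(out / "manifest.json")
        raise
    manifest.to_json(out / "manifest.json")
    return manifest
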