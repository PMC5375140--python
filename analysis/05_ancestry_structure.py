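#!/usr/bin/env python
"""Population structure and mito-nuclear ancestry.

Four views of structure:
1. three-population check — EM admixture at K=3 on a simulated
   focal + two-outgroup dataset thinned to >100 bp (recent admixture
   into the focal population should be minimal);
2. model-order selection on the outlier panel (Evanno ΔK with K=1
   guard over K = 1..5, three seeds each);
3. BIC cluster-number curve on the outlier panel vs all SNPs;
4. supervised southern-ancestry score + EM K=2 Q on the outlier
   panel, and the four-way mito-nuclear classification.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mitoscan import gio
from mitoscan.ancestry import (
    align_q_columns,
    best_of_seeds,
    classify_mito_nuclear,
    cluster_bic,
    em_admixture,
    select_k,
    supervised_mt_score,
)
from mitoscan.containers import GenotypeMatrix
from mitoscan.gio import thin_by_distance
from mitoscan.scan import fst_density_compare
from mitoscan.simulate import SimScenario, simulate_three_populations

QC = Path("results/qc")
DATA = Path("results/data")
SCAN = Path("results/scan")
OUT = Path("results/ancestry")
SEED = 17


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    meta = gio.read_metadata(DATA / "metadata.tsv")
    gm = gio.read_vcf(QC / "genotypes_filtered.vcf", metadata=meta)
    stats = pd.read_csv(SCAN / "scan_results.tsv", sep="\t")

    # 1. three-population admixture on thinned SNPs
    sc3 = SimScenario(n_individuals=161, n_loci=4000, seed=SEED)
    gm3 = simulate_three_populations(sc3, divergence=0.10)
    gm3_thin, _ = thin_by_distance(gm3, min_bp=100)
    res3 = best_of_seeds(gm3_thin, 3, seeds=range(SEED, SEED + 3))
    pops = gm3.samples["population"].to_numpy()
    q3 = pd.DataFrame(res3.Q, columns=[f"Q{k}" for k in range(3)])
    q3.insert(0, "sample_id", gm3.samples["sample_id"])
    q3.insert(1, "population", pops)
    q3.to_csv(OUT / "three_population_q.tsv", sep="\t", index=False)
    focal = res3.Q[pops == "MK"]
    own = focal.mean(axis=0).argmax()
    admix_frac = 1.0 - focal[:, own]
    print(f"3-population EM (K=3, {gm3_thin.n_loci} thinned SNPs): focal mean "
          f"admixture {100 * admix_frac.mean():.1f}%, max {100 * admix_frac.max():.1f}%")

    # 2. Evanno delta-K on the outlier panel
    panel = gm.take_loci(stats["outlier"].to_numpy())
    runs = {
        k: [em_admixture(panel, k, seed=s).loglik for s in range(SEED, SEED + 3)]
        for k in range(1, 6)
    }
    sel = select_k(runs)
    sel.table.to_csv(OUT / "k_selection.tsv", sep="\t", index=False)
    print(f"outlier panel ({panel.n_loci} SNPs): chosen K = {sel.chosen_k} "
          f"by {sel.rule}")

    # 3. BIC cluster number: outlier panel vs all SNPs
    bic_panel, best_panel = cluster_bic(panel, max_k=5, seed=SEED)
    bic_all, best_all = cluster_bic(gm, max_k=5, seed=SEED)
    bic_panel.assign(input="outlier_panel").pipe(
        lambda a: pd.concat([a, bic_all.assign(input="all_snps")])
    ).to_csv(OUT / "cluster_bic.tsv", sep="\t", index=False)
    print(f"BIC cluster number: outlier panel -> K = {best_panel}; "
          f"all SNPs -> K = {best_all}")

    # 4. ancestry scores and the four-way classification
    score = supervised_mt_score(panel)
    em2 = best_of_seeds(panel, 2, seeds=range(SEED, SEED + 3))
    score["q_south_em"] = align_q_columns(em2.Q, score["q_south"].to_numpy())
    score.to_csv(OUT / "ancestry_q.tsv", sep="\t", index=False)
    # classification uses the EM (STRUCTURE-style) Q: the raw allele-sharing
    # score compresses toward 0.5 at the study's per-locus |dp|, so the
    # 0.30/0.70 rule is only meaningful on the model-based fraction
    assign = classify_mito_nuclear(
        score["q_south_em"].to_numpy(),
        panel.samples["mt_haplotype"].to_numpy(),
        sample_ids=panel.samples["sample_id"].to_numpy(),
    )
    assign.to_csv(OUT / "mito_nuclear_groups.tsv", sep="\t", index=False)
    counts = assign["group"].value_counts()
    n_mixed = int(counts.get("NorthMito-Mixed", 0) + counts.get("SouthMito-Mixed", 0))
    print("four-way groups: " + ", ".join(f"{g}: {c}" for g, c in counts.items()))
    print(f"mixed-ancestry individuals: {n_mixed}")
    print(f"supervised vs EM Q correlation: "
          f"r = {np.corrcoef(score['q_south'], score['q_south_em'])[0, 1]:.3f}")

    truth = pd.read_csv(DATA / "truth_samples.tsv", sep="\t")
    merged = assign.merge(truth, on="sample_id")
    agree = (merged["group"] == merged["true_group"]).mean()
    print(f"agreement with simulated truth groups: {100 * agree:.1f}%")

    # 5. within- vs between-population F_ST densities: an external
    # population drifted off the focal south group at the same loci
    rng = np.random.default_rng(SEED)
    d = gm.dosages
    typed = ~np.isnan(d)
    south = gm.samples["mt_haplotype"].to_numpy() == "south"
    p_south = np.clip(
        np.nansum(d[south], axis=0) / (2 * typed[south].sum(axis=0)), 0.02, 0.98
    )
    f_drift = 0.05
    p_ext = np.clip(
        rng.beta(p_south * (1 - f_drift) / f_drift, (1 - p_south) * (1 - f_drift) / f_drift),
        1e-6, 1 - 1e-6,
    )
    ext_d = rng.binomial(2, np.broadcast_to(p_ext, (40, gm.n_loci))).astype(float)
    gm_ext = GenotypeMatrix(
        dosages=ext_d,
        loci=gm.loci.copy(),
        samples=pd.DataFrame(
            {"sample_id": [f"EXT_{i:03d}" for i in range(40)],
             "mt_haplotype": "unknown", "population": "EXT"}
        ),
    )
    outlier_ids = set(stats.loc[stats["outlier"], "locus_id"])
    dens = fst_density_compare(gm, gm_ext, outlier_ids=outlier_ids)
    dens.groupby("comparison")["fst"].describe().to_csv(
        OUT / "fst_density_summary.tsv", sep="\t"
    )
    med = dens.groupby("comparison")["fst"].median()
    print("median F_ST by comparison: "
          + ", ".join(f"{k}: {v:.4f}" for k, v in med.items()))


if __name__ == "__main__":
    main()
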