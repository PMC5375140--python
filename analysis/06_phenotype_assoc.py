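#!/usr/bin/env python
"""Does the mito-nuclear combination predict OxPhos function?

Two tests on State-3 respiration, both controlling for body mass,
acclimation temperature, assay temperature and 3-population admixture:
an ANCOVA with the four-way mito-nuclear group as main effect
(Tukey–Kramer post hoc with compact letters), and a partial regression
of respiration on the southern-ancestry fraction.
"""

from pathlib import Path

import pandas as pd

from mitoscan import gio
from mitoscan.phenotype import ancova_groups, regress_ancestry

DATA = Path("results/data")
ANC = Path("results/ancestry")
OUT = Path("results/assoc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pheno = gio.read_metadata(DATA / "metadata.tsv")
    groups = pd.read_csv(ANC / "mito_nuclear_groups.tsv", sep="\t")
    qtab = pd.read_csv(ANC / "ancestry_q.tsv", sep="\t")

    res = ancova_groups(pheno, groups)
    res.anova.to_csv(OUT / "ancova_table.tsv", sep="\t")
    res.tukey.to_csv(OUT / "tukey_table.tsv", sep="\t", index=False)
    print(f"ANCOVA four-group effect: p = {res.p_value:.4f} (n = {res.n_used})")
    print("Tukey letters: " + ", ".join(f"{g}: {l}" for g, l in sorted(res.letters.items())))

    # regress on the EM (STRUCTURE-style) southern-ancestry fraction
    reg = regress_ancestry(
        pheno, qtab.set_index("sample_id")["q_south_em"].rename("q_south")
    )
    pd.DataFrame(
        [{"slope": reg.slope, "se": reg.slope_se, "r2": reg.r2,
          "p_value": reg.p_value, "n": reg.n_used}]
    ).to_csv(OUT / "regression_summary.tsv", sep="\t", index=False)
    print(f"State-3 ~ southern ancestry (partial): slope = {reg.slope:.3f} "
          f"± {reg.slope_se:.3f}, R² = {reg.r2:.3f}, p = {reg.p_value:.4f}")


if __name__ == "__main__":
    main()
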