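# mitoscan

Tools for asking whether the mitochondrial and nuclear genomes of a
single natural population co-vary — and whether that covariation has a
physiological consequence.

A population that segregates for two deeply diverged mitochondrial
haplotypes (here the northern and southern mtDNA clades of the killifish
*Fundulus heteroclitus*) offers a natural experiment: if selection acts
on mito-nuclear interactions, nuclear loci that interact with the
mitochondrion should show allele-frequency differences between carriers
of the two mt-haplotypes, even inside one panmictic population.
`mitoscan` implements the full chain of that analysis:

1. **wF_ST scan** — per-SNP Weir–Cockerham θ̂ = a/(a+b+c) treating the
   two mt-haplotype carrier groups as artificial subpopulations;
2. **heterozygosity-stratified permutation outlier test** — individuals
   are reshuffled into two groups of the observed sizes, θ̂ recomputed,
   and each locus judged one-sided against permuted values from loci of
   similar He, with BH-FDR and Bonferroni flags on top;
3. **Fisher-exact cross-check** on the 2×2 allele-count tables and the
   overlap of the two outlier sets;
4. **ancestry** — an EM for the admixture likelihood
   Σ [g log(Σ_k q_ik p_kl) + (2−g) log(Σ_k q_ik (1−p_kl))]
   (Q fractions, cluster frequencies P, Evanno ΔK model-order rule) and
   a supervised polygenic score over the outlier panel;
5. **four-way mito-nuclear classification** — north/south mt ×
   pure/mixed nuclear ancestry at the 30% rule;
6. **phenotype stage** — State-3 mitochondrial respiration residualized
   on body mass, acclimation temperature, assay temperature and
   admixture, then tested by four-group ANCOVA (type-II SS,
   Tukey–Kramer post hoc) and by partial regression on the
   southern-ancestry fraction Q_south.

Because the GBS genotypes behind the original study were never
deposited, the package ships a first-class synthetic-data generator
whose defaults encode the study conditions (155 individuals at a 60/40
south/north mt ratio; 11,705 SNPs on ~10,180 scaffolds; 349 planted
loci at mean between-mt-group |Δp| = 0.112 over a 0.033 background;
MiAF ≈ 0.13–0.16; a phenotype with 6% of variance explained by
southern ancestry) together with ground-truth tables for every planted
locus and every individual's true ancestry.  See `docs/methods.md` for
the model, calibrations and limitations.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_cohort.py   # cohort + truth tables -> results/data/
python analysis/02_qc_filter.py         # MAF / call-rate / excess-het QC
python analysis/03_outlier_scan.py      # wF_ST scan + permutation null + Fisher
python analysis/04_ld_tajima.py         # LD and Tajima's D side analyses
python analysis/05_ancestry_structure.py
python analysis/06_phenotype_assoc.py
```

On the seed shipped in the scripts this prints (abridged):

```
cohort: 155 individuals x 11705 SNPs (93 south-mt / 62 north-mt)
realized mean |dp| mt-groups: planted 11.13% vs background 4.40%
loci: 11705 in -> 11662 retained (MAF removed 24, call-rate 0, excess-het 19)
outliers: 805 at p<0.01, 526 at FDR 10%, 62 at FDR 1%, 0 Bonferroni
Fisher p<0.01: 670; overlap with scan outliers: 667 (Jaccard 0.83)
planted recovery: 155/349 planted among 805 calls (hypergeometric p 2.73e-89)
mean wF_ST planted 0.0460 vs background 0.0066
3-population EM (K=3, 3925 thinned SNPs): focal mean admixture 3.2%, max 9.8%
outlier panel (805 SNPs): chosen K = 2 by delta-K
BIC cluster number: outlier panel -> K = 2; all SNPs -> K = 2
four-way groups: SouthMito-SouthNuc: 88, NorthMito-NorthNuc: 59,
                 SouthMito-Mixed: 5, NorthMito-Mixed: 3
median F_ST by comparison: north_vs_external: 0.0122, south_vs_external: 0.0056,
                           within_nonoutlier: -0.0007, within_outlier: 0.0542
ANCOVA four-group effect: p = 0.0024 (n = 155)
State-3 ~ southern ancestry (partial): slope = 0.575 ± 0.182, R² = 0.061, p = 0.0020
```

Reading this: the planted mito-nuclear loci carry the intended ~11%
between-mt-group frequency difference against a ~4.4% realized
background (a 3.3% true difference plus binomial sampling noise at
n = 62/93); the permutation scan calls them far beyond chance (the
hypergeometric enrichment p is the probability of that many planted
loci among the calls if calls were random); the focal population shows
only ~3% admixture with the two outgroups; ΔK and BIC both recover the
two-cluster structure of the outlier panel, with a minority of
mixed-ancestry individuals; and the phenotype stage finds a significant
four-group effect and a positive partial slope of respiration on
southern ancestry, with R² near the 6% of variance the generator
plants.  The density comparison makes the scan's point in one line: the
outlier panel's *within-population* wF_ST (median 0.054) is larger than
the *between-population* F_ST at the same loci, which ordinary
demography does not produce.

A single-command version of the same pipeline, driven by a flat YAML
config with per-stage checksums in a run manifest:

```bash
mitoscan run --out-dir results/run --seed 1
```

plus subcommands `simulate`, `filter`, `stats`, `ld`, `tajima`, `scan`,
`ancestry`, `assoc` for the individual stages (`mitoscan --help`).

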