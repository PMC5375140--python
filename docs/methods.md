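# Methods

## Problem and model

A single estuarine *Fundulus heteroclitus* population can segregate for two
deeply diverged mitochondrial lineages ("northern" and "southern"
mt-haplotypes).  If mito-nuclear epistasis is under selection, nuclear loci
that interact with the mitochondrial genome should show allele-frequency
differences between carriers of the two mt-haplotypes even though the
population is otherwise panmictic.  The package implements that scan and its
downstream consequences:

1. **wF_ST scan.**  Treating the two mt-haplotype carrier groups as
   artificial subpopulations, each biallelic SNP gets a Weir–Cockerham
   (1984) variance-components estimate θ̂ = a/(a+b+c), with a, b, c the
   among-group, among-individual-within-group and within-individual
   components.  Missing genotypes are excluded per locus with per-group
   sample sizes recomputed; negative θ̂ are reported as-is (the bulk of a
   null distribution is slightly negative).  The multilocus estimate is the
   ratio of sums Σa/Σ(a+b+c).
2. **Heterozygosity-stratified permutation null.**  Individuals are
   randomly reassigned to two groups at the observed mt-group sizes
   (without replacement), θ̂ is recomputed for every locus, and permuted
   values pool into equal-count bins of expected heterozygosity (He),
   because the sampling dispersion of θ̂ depends strongly on He.  The
   one-sided upper-tail p for a locus is (b+1)/(m+1) over the null values
   of its own He bin (add-one rule: p is never 0); bins with fewer than
   200 null values merge with a neighbour.  Outliers are flagged at raw
   p < 0.01, Benjamini–Hochberg FDR 10% and 1%, and Bonferroni at the same
   family-wise level as the raw threshold (0.01/m), which makes the four
   flag sets nested.
3. **Fisher-exact cross-check.**  Per locus, a two-sided Fisher exact test
   on the 2×2 minor/major × mt-group allele-count table; concordance with
   the scan is summarised by overlap, Jaccard, and a hypergeometric
   enrichment p.
4. **Ancestry.**  Two estimators of a per-individual southern-ancestry
   fraction from the outlier panel: (a) a supervised polygenic score — the
   fraction of an individual's typed panel alleles that are
   "south-associated" (the allele at higher frequency among southern-mt
   carriers; orientation re-derived from the data, so the score is
   invariant to ref/alt flips); (b) an unsupervised EM maximising the
   standard admixture binomial likelihood
   Σ_{i,l} [g·log(Σ_k q_ik p_kl) + (2−g)·log(Σ_k q_ik(1−p_kl))] with
   missing entries contributing nothing and frequencies clamped to
   [1e−6, 1−1e−6].  The EM update is the exact M-step, so the
   log-likelihood is monotone; label switching is resolved by greedy
   matching of cluster-frequency rows (or, for K=2, by correlation with a
   reference fraction).  Several seeded starts are run and the best
   likelihood kept.  Model order uses the Evanno ΔK rule with a K=1 guard:
   choose argmax mean log-likelihood if that is 1, else argmax
   ΔK = mean|L(K+1) − 2L(K) + L(K−1)| / SD(L(K)), ties toward smaller K.
5. **Four-way classification.**  A northern-mt individual with ≥ 30%
   southern nuclear ancestry is "NorthMito-Mixed", otherwise
   "NorthMito-NorthNuc"; symmetrically for southern-mt.  The boundary is
   inclusive ("at least 30% of alleles from the opposite cluster").
6. **Phenotype stage.**  State-3 respiration (ADP- and
   substrate-stimulated mitochondrial O₂ consumption, pmol O₂ s⁻¹ ml⁻¹
   per ng DNA) is residualized by OLS on body mass (continuous),
   acclimation temperature (categorical, {12, 28} °C), assay temperature
   (categorical, {12, 20, 28} °C) and the 3-population admixture fraction.
   The four-way group is tested by ANCOVA with type-II sums of squares
   (the design is unbalanced) and Tukey–Kramer pairwise comparisons of the
   covariate-adjusted group means, with adjusted p from the exact
   studentized-range distribution and a compact letter display.  The
   ancestry regression is a partial regression (both phenotype and
   ancestry residualized on the covariates), so by Frisch–Waugh–Lovell the
   slope equals the coefficient of ancestry in the full joint model.

Side analyses: pairwise LD in a 50-SNP sliding window (r² from dosage
correlation over jointly typed individuals; D′ from a two-locus
phase-unknown EM for haplotype frequencies, normalised by D_max; p from
χ²₁ = 2n·r²), and Tajima's D in 50-bp non-overlapping windows per scaffold
(unbiased per-site π, sequence count 2× the minimum typed diploids across
the window's sites, D undefined at S = 0).

## Synthetic cohorts

No genotype data are distributed with the study this emulates, so the
generator is a first-class, tested module.  Its defaults are the study's
conditions: 155 individuals at a 60/40 southern/northern mt ratio
(93/62), 11,705 SNPs over 10,180 scaffolds, 349 planted loci with mean
between-mt-group |Δp| = 0.112 against a 0.033 background, ~8% missing
calls, and a phenotype effect of 0.06.

* **Baseline frequencies.**  Minor-allele frequencies draw from a
  Beta(1.5, 8.5) truncated to [0.01, 0.5] (mean ≈ 0.15), giving mean
  He ≈ 0.2 — matching the study's reported MiAF (0.13–0.16) and He
  (0.20–0.23) ranges.
* **Between-group differences are ancestry-mediated.**  Each
  individual carries a true southern-ancestry fraction q: most sit near
  0 or 1 (Beta(2,30)/Beta(30,2) by mt-haplotype), a minority (≈ 21/155)
  draws uniformly from (0.3, 0.7).  Every locus gets two
  ancestry-cluster frequencies ± δ*/2 around a base frequency
  (direction random), with δ* = δ/(q̄_S − q̄_N) so the realized
  *between-mt-group* difference is centred on the configured δ;
  genotypes are binomial in the individual's ancestry-mixed frequency
  q·p_S + (1−q)·p_N.  Background loci draw δ around 0.033 and planted
  loci around 0.112 (per-locus SD 30% of the mean — the dispersion of
  the between-group difference is not reported anywhere, so it is an
  exposed free parameter).  Mediating *all* differences through q, not
  only the planted ones, matters: in a panmictic population a genuine
  mt-group frequency difference can only be carried by individuals,
  and a label-linked background would make the outlier panel's
  structure perfectly discrete, collapsing every EM ancestry fraction
  to 0/1 and erasing the mixed-ancestry class.  Frequencies outside
  (0,1) are resampled; an infeasible δ raises.
* **Phenotype.**  y = intercept + β_mass·mass + β_acc·acclim +
  β_assay·assay + β_q·q + N(0, σ²), with mass log-normal (median 8 g),
  temperatures uniform over their level sets, and β_q solved so the
  *expected sample R²* of the residualize-then-regress path equals the
  configured effect: residualization shrinks the ancestry sum of squares
  by κ = (n−p)/(n−1) in expectation (p = 6 covariate parameters) and the
  one-predictor sample R² is upward-biased, so β_q solves
  E[R²] ≈ (λ+1)/(λ+n−p) with λ = β_q²·κ·S_qq/σ² — not the naive
  population-ρ² identity, which would under- or over-shoot by several
  Monte-Carlo standard errors at n = 155.
* **Three-population cohorts** add two outgroups by Balding–Nichols
  draws (Beta with variance F·p(1−p)) around a shared ancestral
  frequency; the focal population sits at the ancestral frequency and
  carries both mt-haplotypes.  The multilocus Weir–Cockerham θ between
  two outgroups each drifted F converges to F itself.

What the generator does **not** emulate: linkage beyond "mostly unlinked"
(no coalescent or recombination model — within-tag SNP pairs are placed
10–64 bp apart but their genotypes are conditionally independent given
ancestry; conversely, because every locus loads weakly on the shared
ancestry fraction, there is a faint *genome-wide* LD component that real
data would not show, so the LD analysis on synthetic data measures
calibration, not the study's short-range LD signal); structured
missingness (the study's call-rate pattern is unreported, so missingness
is uniform); read-level GBS artefacts; and any direct mt-genotype effect
on the phenotype beyond the ancestry channel.
Passing tests therefore demonstrate statistical correctness and
calibration of the machinery, not re-discovery of the study's exact
counts, which depended on an unreleased dataset and a coalescent null.

## Numerical and design choices

* **Outlier null.**  The original analysis drew its outlier p-values from
  a coalescent FDIST null conditioned continuously on heterozygosity; this
  package substitutes the He-stratified permutation null (which the study
  itself used for validation).  Exact reproduction of the printed outlier
  counts is therefore out of reach by construction; the scan is judged on
  type-I calibration and planted-locus recovery instead.
* **Filter boundaries.**  MAF and call-rate thresholds are inclusive on
  the keep side (a locus at exactly 1% MiAF or 70% call rate is
  retained); filter order is fixed MAF → call rate → excess-het HWE →
  thinning, with a doubly-failing locus attributed to the earliest
  filter.  The excess-het test is the one-sided exact (Levene–Haldane)
  heterozygote-excess tail, applied only where Ho > He.
* **Composite LD.**  r² uses dosage correlation (its null expectation is
  1/(n−1) for n diploids); D′ comes from the two-locus EM; the LD p-value
  treats 2n·r² as χ²₁ — the convention of the GBS toolkit the study used,
  noted as an assumption.
* **Cluster-number BIC.**  The k-means solution is scored as a
  hard-assignment spherical Gaussian mixture:
  BIC = −2·loglik + [(K−1) + K·d + 1]·log(n) on d retained principal
  components.  A penalty that grows only with K (not with the K·d centre
  parameters) cannot work here: splitting a spherical cluster in d
  dimensions cuts its within-cluster sum of squares by ≈ 2/(πd)
  regardless of structure, which beats any log(n) penalty on the
  n·d·log(WSS) scale, making such criteria monotone in K.  The full
  parameter count restores a minimum at the true K and is invariant to
  duplicating individuals.
* **Permutation scale.**  The package defaults to 1,000 permutations (the
  study's choice); the analysis scripts and acceptance checks run 200
  (p-value resolution 1/201 < 0.01), which keeps the full 11,705-locus
  scan under ~15 s while leaving the raw p < 0.01 call set
  well-resolved.  A side effect of any finite permutation null: the
  smallest attainable p is 1/(m+1) for an m-value He bin, so the
  Bonferroni flag (p < 0.01/11,705 ≈ 8.5e−7) cannot fire unless a bin
  pools over ~10⁶ permuted values; its count is reported as computed,
  which at these scales is 0.
* **Degenerate inputs.**  Monomorphic loci: MiAF = He = 0, θ̂ undefined
  (flagged, not zero); LD pairs with a monomorphic member are skipped;
  Tajima windows with S = 0 carry an undefined D; a locus where a group
  has < 2 typed individuals gets no θ̂; empty p-vectors return empty
  q-vectors.
* **Determinism.**  Every stochastic operation takes an explicit seed and
  draws from a single `numpy.random.default_rng`; the pipeline manifest
  records per-stage output checksums, and identical configs reproduce
  identical checksums.

## Problem sizes

The test suite and acceptance checks use the study-scale cohort
(155 × 11,705, 200 permutations) for the scan properties, the stated
reduced scales elsewhere (2,000 loci for null calibration; 300-locus
two-population mixtures for EM recovery; 200 phenotype replicates at
n = 155; 500 reduced-n replicates for ANCOVA null calibration), and
Fisher/Weir–Cockerham/BH/Tajima oracle equivalence on exhaustive small
tables and 1,000 random 8-individual instances.

## Known limitations

* The permutation null conditions on binned, not continuous, He; very
  sparse bins merge, which coarsens the conditioning at the He extremes.
* The supervised score and the EM Q are both computed from the same
  outlier panel selected on the same data, so — as in the original
  design — the ancestry structure of the panel is partly circular; the
  phenotype stage inherits that caveat.
* Planted loci in the generator end up with slightly *higher* realized
  MiAF/He than null loci (mixing two cluster frequencies pushes
  frequencies toward the middle), whereas the study reports slightly
  lower outlier MiAF; no acceptance property depends on this contrast.
* The EM admixture model has no correlated-allele-frequency prior and no
  admixture-LD terms; it replaces both external structure programs with
  one likelihood.
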