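# Methods

This note documents the statistical model behind `prcgwas`, the design
decisions taken where the procedure was genuinely open, the synthetic-data
generator's assumptions, and the package's numerical conventions and
limitations.

## Phenotype model

Thickness is indexed by individual, PRC layer (ONL, IS, OS), ETDRS segment
(central subfield C; inner ring IS1–IS4; outer ring OS1–OS4) and eye (L/R),
in micrometres.  Analysis phenotypes are built in a fixed order:

1. **Eye-level residualization.** For each eye separately, thickness is
   regressed (OLS with intercept) on the eye-specific covariates: image
   quality score, the five segmentation indicators (ILM indicator, valid
   count, minimum motion correlation, maximum motion delta, maximum motion
   factor) and refractive error (*spherical + 0.5 × cylindrical*, in
   diopters).  Residuals keep the sample mean as an offset so values remain
   interpretable in µm; the offset does not affect any association
   statistic.  Collinear covariate columns are dropped with a warning.
2. **Eye averaging.** The mean of available eyes; single-eye individuals
   are retained with the available eye and flagged rather than dropped
   (dropping would silently shrink cohorts).
3. **Scope aggregation.** Unweighted mean over the whole grid, a concentric
   field (foveal = {C}, intermediate = inner ring, peripheral = outer
   ring), or a single segment.  Unweighted (rather than ETDRS-area-
   weighted) means are the simplest faithful choice.

Because the covariate design is shared by all segments of an eye and both
residualization and averaging are linear operators, residualizing per
segment and aggregating afterwards is *exactly* equivalent to aggregating
first; the fixed order is therefore canonical, and the test suite verifies
both the equivalence and that eye-specific designs make the naive
average-then-residualize order genuinely different.

Segment ring labels follow scan order; no laterality-aware nasal/temporal
flip is applied between eyes (no rule is defined for it, and all shipped
analyses aggregate symmetric scopes).

## Cohort QC

Filters run in a fixed order, each exclusion attributed to the first
applicable filter: (1) ancestry — keep individuals within Euclidean
distance 1.45×10⁻³ (inclusive boundary) of the reference centroid
(7.52×10⁻⁴, −4.66×10⁻⁴) in PC1–PC2 space; (2) relatedness — a precomputed
exclusion list (kinship estimation is out of scope); (3) image quality —
remove individuals with any imaged eye's quality score strictly below 45;
(4) per indicator, remove individuals strictly worse than the 20% quantile
of the surviving population (low tail for ILM indicator, valid count and
minimum motion correlation; high tail for the two motion maxima), using the
per-individual worst eye; (5) refractive error — remove individuals with
any eye outside median ± 1.5 × IQR of the surviving population (pooled over
eyes).

Decisions worth recording:

* The refractive-error outlier rule is implemented as the window
  median ± multiplier × IQR with the multiplier configurable (default 1.5);
  other readings of "one standard deviation of 1.5 times the IQR" exist and
  this one is documented rather than asserted as uniquely correct.
* The 20% indicator cut is computed *after* the quality-score cut, on the
  surviving population.
* Quantile ties at the threshold are retained, so a population with
  constant indicator values is never decimated.  A consequence: on
  continuous indicator data the quantile rule re-estimates its cut from the
  current population and is not a strict fixed point under reapplication;
  idempotency holds (and is tested) on data whose retained mass is tied at
  the threshold, as produced by the `qc_mixed` fixture.
* PCA on genotypes (LD pruning at 50 kb window / step 1 / r² < 0.8,
  MAF > 0.1, then SVD of standardized dosages) is provided as a utility for
  synthetic panels; the primary path consumes precomputed PCs, matching how
  biobank PCs are consumed in practice.

## Association engine

One OLS engine serves the common-variant GWAS, the gene-burden tests, the
per-segment effect maps and the interaction models: phenotype on predictor
+ covariates (age, weight, sex, height, OCT machine ID one-hot, top
genotype PCs) + intercept.  p-values are two-sided from the t distribution
with residual degrees of freedom (large-sample normal approximations differ
negligibly at cohort n; the t choice is exact in small simulations).
SNPs with complete dosages are fitted by Frisch–Waugh–Lovell: phenotype and
dosage matrix are residualized on the covariate block once, then each SNP
needs a scalar regression.  This is algebraically identical to the full
per-SNP fit (verified against a normal-equations oracle to 10⁻⁸) and keeps
scans vectorized.  Per-SNP missing dosages fall back to complete-case full
fits (mean imputation available by flag).  Monomorphic SNPs are flagged
with p = 1 by convention; zero-residual fits are flagged degenerate with
SE = 0 and p clipped to the smallest positive float so p ∈ (0, 1] holds.

Dosage counts the ALT (A1) allele; flipping the coded allele negates β and
preserves SE and p (tested).

**Meta and loci.** The meta p across layers is the minimum of the three
layer p-values (source layer recorded, ties to ONL→IS→OS order); a
dedicated multi-trait meta-analysis model is external prior art and out of
scope.  An optional ×3 Bonferroni on the min is available but off by
default, the 5×10⁻⁸ threshold being applied to the meta p as-is.
Independent loci are selected greedily by distance — take the smallest-p
significant SNP, suppress significant SNPs within 10 Mb on the same
chromosome, repeat — replacing conditional-joint analysis, whose role here
is only the selection geometry; selected leads within 1.5 Mb share a locus
group label.  Ties in p break deterministically by (CHR, POS, ID), making
the selection invariant to input order.

**λ_GC** = median(χ²_obs) / median(χ²₁) with χ²_obs = Q⁻¹(p; 1 df).  Note
the median of 500 draws has Monte-Carlo sd ≈ 0.107·λ, so per-scan values on
small panels scatter widely around 1 even under a perfect null; pooled
p-values are the meaningful diagnostic at that scale.

## Concentric-field differential effects

For each layer and ordered field pair (foveal–intermediate,
foveal–peripheral, intermediate–peripheral), SNPs genome-wide significant
in *either* field scan are tested with

Z = |β₀ − β₁| / √(SE₀² + SE₁²),  p = 2·Φ(−Z).

The formula treats the two estimates as independent although both fields
are measured on the same individuals; positively correlated fields make the
test conservative. It is implemented exactly as printed (default), with a
covariance-corrected alternative — regressing the within-individual
between-field difference phenotype on dosage — available for comparison.
Under a shared-effect null with genuinely independent samples the z-test
p-values are uniform (KS-tested at 10⁴ tests).

The Bonferroni family is the number of z-tests actually performed within
one (layer, comparison) family (configurable to the global count; the
family definition is otherwise unstated).  Significant SNPs are clumped:
each is annotated with companions at r² > 0.05 within ±1000 kb (r² =
squared Pearson correlation of dosages in the analysis cohort; no external
reference panel), annotation groups are merged into connected components,
and the lowest-p member (ties by position then ID) is the lead.

Per-segment effect maps refit the additive model on each of the nine
residualized eye-averaged segment phenotypes and render a bullseye heatmap
with a diverging scale symmetric about zero, normalized per SNP.

## Rare-variant burden

Qualifying sets per gene: high-confidence LoF; missense with both SIFT
"deleterious" and PolyPhen "probably_damaging".  Both restricted to minor
allele frequency strictly < 1%, computed from the analysis cohort by
default (annotation-supplied population AF usable instead).  Collapsing per
(gene, class): 0 = no qualifying variant; 1 = ≥ 1, all heterozygous; 2 =
any qualifying variant homozygous for the rare allele.  Phase is ignored
and compound heterozygotes are not modelled; LoF and missense are tested
separately, never combined.  Genes with zero carriers are flagged
untestable and excluded from multiple-testing counts.  Suggested threshold
5×10⁻⁵.

## Interactions and enrichment

Interaction tests fit y ~ g₁ + g₂ + g₁·g₂ + covariates and report the
product term; g₁ may be a dosage, a collapsed burden genotype, or 0/1
genetically defined sex (when sex is both a covariate and an interactor the
duplicated main-effect column is dropped, leaving the correct model).  A
battery pools its categories (anchor × leads, pairwise sets, leads × sex,
burden × nearby SNPs) into one Benjamini–Hochberg family at FDR < 0.15
(per-category adjustment available; the family definition is otherwise
open).  Untestable pairs are reported but excluded from the family.

Disease-gene overlap uses the exact inclusive upper tail of the
hypergeometric distribution, P(X ≥ k) for N items, K listed, n tested; the
universe and list are inputs.

Stratified grid means: within each anchor-genotype stratum, per-(partner
genotype, segment) mean raw thickness (eye-averaged) minus the stratum
grand mean over all its individuals × segments — so each 3×3 panel cell
shows deviation in µm from its stratum's average, and the count-weighted
cell means sum to zero within a stratum by construction.

## Synthetic-data generator

The generator emulates the statistical structure of the study data, not its
biology:

* **Genotypes.** Two independent haplotypes per individual; within an LD
  block each haplotype copies the previous SNP's allele with probability
  `ld_rho` (default 0.3, blocks of 10), else redraws at that SNP's
  frequency (uniform on 0.05–0.5 by default).  Haplotype independence
  keeps every SNP in Hardy–Weinberg proportions at any LD strength; r² is
  tunable without a reference panel.  Positions are laid out at 50 kb
  steps over a configurable number of chromosomes.
* **Phenotypes.** baseline(layer, segment) + covariate effects + Σ planted
  dosage·β(segment) + β_int·dosage·dosage (interaction layer) + optional
  burden offsets + individual noise (shared across eyes; default 2 µm) +
  eye noise (default 1 µm).  Baselines are realistic layer profiles (ONL
  thickest at the fovea).  Covariates: age uniform 40–69 years (the
  recruitment range), sex Bernoulli(0.5), height/weight normal with
  sex-specific means, three OCT machines, per-eye refraction and
  image-QC indicators from configurable normals with an optional
  poor-quality fraction shifted in the failing direction.  No generative
  model for these is published; the defaults are placeholders with stated
  units.  QC indicators are generated independently of true thickness
  (their joint distribution is unknown), so passing QC tests demonstrates
  the filter mechanics, not the epidemiology of image quality.  One eye
  can be dropped for a configurable fraction to exercise the averaging
  contract.
* **Population structure.** PC1–PC2 main cluster strictly inside the
  ancestry radius around the reference centroid; outliers placed beyond
  2.2× the radius; higher PCs small isotropic noise.
* **Rare variants.** Per-variant binomial(2, f) carriers at f < 0.01 with
  VEP/LOFTEE-style annotation rows; optional decoys (benign missense,
  low-confidence LoF, too-common variants) so classification has something
  to reject.  Planted burden effects enter the phenotype through the same
  collapsing rule the analysis uses.

Presets: `null` (no effects), `differential` (foveal-only ONL effect 1.2 µm
at MAF 0.3, uniform ONL effect 0.6 µm, burden effects +2.0/−1.5 µm),
`interaction` (two uniform effects plus a 0.6 µm·copy² product term),
`burden`, and `qc_mixed` (550 individuals with 30/15/12/10/8 planted
ancestry/relatedness/quality/indicator/refraction failures and 475 clean
survivors, constructed so every planted count is recovered exactly and the
workflow is idempotent).  All presets are deterministic per (preset, seed);
planted MAFs are fixed at 0.3 so detection power does not depend on a
random frequency draw.

What the generator does **not** emulate: imputation dosage uncertainty,
X-chromosome conventions, realistic OCT images, correlated QC indicators,
genuine population stratification of phenotypes, or linkage between the
rare-variant genes and the common-variant panel.  Green tests therefore
certify the statistical machinery under its stated assumptions, not
robustness to every artefact of real cohorts.

## Numerical conventions and problem sizes

* Degenerate (zero-residual) fits are detected at rss ≤ 10⁻¹² × total sum
  of squares, the cancellation scale of the vectorized residual update.
* Monomorphic predictors are detected at dosage variance ≤ 10⁻²⁰·n.
* All tie-breaks (min-p layers, locus selection, clump leads) are
  deterministic and documented above.
* Randomness flows from one master seed split per stage with
  `numpy.random.SeedSequence`.
* The shipped presets use 2,000 individuals × 500 SNPs (100–200 SNPs for
  QC/burden-focused presets); simulation-based tests use 400–5,000
  individuals and up to 10⁴ SNP tests per property.  These sizes give the
  planted effects z-scores of 6–20, so recovery checks are far from
  marginal while whole-suite runs stay in minutes.

## Known limitations

The min-p meta is not a calibrated joint test (no correction for the
correlation between layers; an optional ×3 Bonferroni is provided).
Distance-greedy locus selection reproduces selection geometry, not
conditional independence.  The differential z-test ignores between-field
covariance by design (see above).  Burden testing has no dispersion
(SKAT-style) component and no compound-heterozygote handling.  Enrichment
requires the caller to define the gene universe.
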