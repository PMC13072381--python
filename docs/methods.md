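# Methods

This note documents the models implemented in `specklemap`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Mixed major-gene + polygene segregation analysis

### Model family

An F2 speckle count y is modelled as a mixture of normals.  The mixing
proportions are the Mendelian F2 genotype-class frequencies and are never
estimated: (¼, ½, ¼) for one major locus; the product weights
(1,2,1,2,4,2,1,2,1)/16 for two independent loci.  Component means are
linear in the genetic effects — population base m, additive effects
d (per locus), dominance effects h (per locus):

    μ(class) = m + x_a·d_a + z_a·h_a + x_b·d_b + z_b·h_b,

with x ∈ {1, 0, −1} the homozygote dose and z ∈ {0, 1} the heterozygote
indicator.  Constraint suffixes define the catalog: `-A` (h = 0), `-AD`
(all free), `-EA` (d_a = d_b, h = 0), `-EAD` (d_a = d_b = h_a = h_b),
`-CD` (h = d per locus), `-NCD` (h = −d).  Equal-mean classes are
collapsed at catalog-construction time (verified against brute-force
enumeration in the tests), e.g. 2MG-EAD collapses to three components
with weights (9, 6, 1)/16 and means m+2d, m, m−2d.

A common within-component variance σ² absorbs environmental noise and, for
the mixed (MX2-\*) models, the polygenic background: with F2 data alone
σ²_pg and σ²_e are not separable, so the MX2 models share the mixture
structure of the corresponding two-major-gene model and report
σ²_pg = max(0, σ̂² − σ²_e) only when the caller supplies an environmental
variance σ²_e (from parental or F1 samples).  A single-component
pure-polygene model (`PG`) closes the catalog.

### Fitting

EM with fixed weights: the E-step computes class responsibilities; the
M-step solves a weighted least-squares problem for the free mean
parameters (normal equations XᵀNX β = Xᵀ(Ry) with N the responsibility
column sums) and pools σ² over all components.  Initialization is a
model-implied quantile split of the sorted data plus seeded random
restarts (default 20; the heavy simulation studies use 3, which the
selection experiments show is sufficient at n = 400).  Convergence:
relative log-likelihood change < 1e−8 or 2000 iterations; variance floor
1e−6 × sample variance; the monotonicity of the log-likelihood is tracked
and asserted in tests.  The likelihood treats the counts as continuous,
as the classical segregation-analysis framework does.

### Model ranking

AIC = −2 lnL + 2k, ascending; ties break by smaller k, then code.  Two
parameter-count conventions are available.  The default `minimal` counts
the free mean parameters plus σ².  The `printed` convention
(`K_AIC_PRINTED`) reproduces the counts used by the classical software,
back-computed from its published lnL/AIC pairs; those counts charge the
fully free two-locus mixture only one parameter more than its equal-effects
special case, which makes selection between nested models nearly a coin
flip (the extra 3 degrees of freedom gain more than 1 AIC unit with
probability ≈ 0.57), so `minimal` is the default and `printed` is provided
for comparability with published rankings.

### Goodness of fit

Diagnostics operate on the probability integral transform of the data
under the fitted mixture.  Counts are rounded observations of a continuous
variable; the plain PIT of rounded data is discrete and mechanically
inflates every uniformity statistic (a correct model is rejected
essentially always at n = 500).  The package therefore uses the
randomized PIT u = F̂(x−½) + V·(F̂(x+½) − F̂(x−½)) with V ~ U(0,1), which
is exactly uniform when the fitted model is correct; the randomization is
seeded for reproducibility, and the seed stream is deliberately decoupled
from the simulator's stream (sharing a small integer seed between
generation and diagnosis would otherwise correlate V with the mixture
class draws).  Statistics: U₁², U₂², U₃² (squared projections on the
orthonormal shifted Legendre polynomials, each χ²(1) under uniformity;
U₁² ≡ 12n(ū−½)²), the Cramér–von Mises nW² and the Kolmogorov Dₙ against
the uniform law.  Measured calibration at n = 500 over 20 replicates:
0–2 rejections per test at α = 0.05.

### Variance decomposition

σ²_mg = Σⱼ wⱼ(μⱼ − μ̄)² from the fitted components; h²_mg = σ²_mg / s²_P
(sample variance, ddof 1), reported in percent and capped to [0, 100].
h²_mg is invariant under affine rescaling of the phenotype.

### Sex comparison

Welch's two-sample t-test on the raw counts, plus a Pearson correlation
between the two sexes' per-count relative-frequency vectors over the union
support — a documented operationalization of "distribution concordance"
(the classical presentation does not define the correlation operationally).

## Synthetic data

The generator defines the study conditions for every simulation-based
check; its defaults are fixed once and are not tuned per test.

* **F2 phenotypes** — a genotype class is drawn from the model's Mendelian
  weights; the count is the class mean plus Gaussian polygenic +
  environmental noise, rounded and clipped at 0.  Rounding adds ≈ 1/12 to
  the within-class variance and clipping is negligible for the default
  means; acceptance tolerances account for this.  Family size is a free
  parameter (the published cross tables suggest n = 9 per sex per family;
  simulation studies here use n = 400–1000 so that asymptotic claims are
  testable).
* **SNP panels** — ancestral allele frequencies ~ U(0.1, 0.9);
  subpopulation frequencies Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F)
  at differentiation F_ST; haplotypes from a first-order Gaussian-copula
  chain along each chromosome thresholded at the subpopulation frequency,
  so adjacent-locus latent correlation decays as ld_rho^distance_kb and
  genotype r² decays ≈ ld_rho^(2·distance_kb); hard subpopulation
  assignment (balanced); dosage 0/1/2 with uniform missingness.  The
  default panel mirrors the emulated design: 120 individuals in 8
  phenotype groups of 15.  The trait is a causal-dosage sum plus Gaussian
  noise scaled to the target heritability, shifted and rounded to a count;
  phenotype-group labels are rank bins of that count.
* **Ct tables** — per biological sample, a reference-gene level and
  target-gene levels tied to it (so ΔCt is well defined), group-specific
  ΔCt shifts on targets only, triplicate technical replicates with small
  jitter.

What the generator does **not** emulate: linked selection, inbreeding and
family structure within subpopulations, genotyping error, allele-frequency
spectra of real resequencing data, realistic gene density/intron length,
or qPCR efficiency below 2.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated generative
assumptions, not performance on real resequencing panels.

## Population genetics

* **Filtering** — remove loci with MAF < 0.05 **or** missingness > 0.5
  (strict inequalities; boundary loci retained; all-missing loci removed
  as uninformative).  Idempotent; a report lists every removal with its
  reason.
* **Kinship** — VanRaden centered GRM with per-locus mean imputation of
  missing dosages.  Note the centered GRM's off-diagonal mean is ≈ −1/(n−1)
  by construction; "unrelated panel off-diagonals → 0" holds as n grows.
* **Admixture** — binomial-likelihood block relaxation (EM updates of Q
  and F) with missing entries dropped from the likelihood.  K is chosen by
  masking random folds of observed genotype entries, refitting, and scoring
  the mean squared deviation between held-out dosage/2 and the predicted
  allele probability; best K minimizes the CV error.  Initialization is
  random Dirichlet Q; a few restarts keep the best likelihood.  Label
  switching is inherent; comparisons against truth are made up to
  permutation.
* **Tree** — p-distance (fraction of mutually non-missing loci with
  different dosage) + Saitou–Nei neighbor joining.  Negative branch
  lengths are clamped to zero with the remainder carried by the sibling
  edge so pairwise path lengths are preserved; on additive inputs the
  reconstruction is exact.
* **LD** — composite r² (squared Pearson correlation of unphased dosage
  vectors) for all intra-chromosome pairs within a maximum distance,
  pairwise deletion for missing data, binned means by distance.  The
  stable distance is the left edge of the first bin from which the 3-bin
  rolling mean changes by less than a relative tolerance across a window.
  The classical block-extension procedure is deliberately not reimplemented;
  the stable-distance readout replaces it.  Both the 250 kb and 500 kb
  distance caps that appear in the published workflow are plain parameters.

## Association models

`glm`: per-locus OLS of the count on dosage, two-sided t-test, vectorized
by residualizing phenotype and dosages on the covariates.  `glmq`: ancestry
proportions appended (one column dropped against the intercept).
`mlmk`/`mlmkq`: exact per-marker REML in the variance ratio
δ = σ_e²/σ_g² after a one-time eigendecomposition of K — a 25-point log
grid over δ ∈ [1e−5, 1e5] followed by bounded Brent refinement — then GLS
and a Wald t-test on the marker effect.  Exact per-marker REML (rather
than estimating variance components once under the null) is affordable at
n ≈ 120 and is the default.  PVE is the squared partial correlation of
the marker given the covariates (computed on the whitened scale for the
mixed models) × 100.  Monomorphic loci are recorded with p = 1 and a
flag.  Significance defaults to Bonferroni α/M; a fixed score cutoff is
available.  λ = median(χ²₁ quantiles of p)/0.45494.  Single-marker "LOD
score" outputs are −log10 p; no likelihood-ratio LOD is computed.

## QTL integration

The QTL mapping is a marker-scan reconstruction (no mapped cross genotypes
exist at this stage of the published workflow): peaks of the −log10 p
profile above a threshold (default Bonferroni) become QTL; the support
interval extends over contiguous markers within 1.5 score units of the
peak.  The alternative "ranking" method groups the top score quantile by
adjacency.  Names are Q-\<prefix\>-\<chrom\>-\<serial\> in genomic order.
All intervals are closed and 1-based; QTN-in-QTL matching and gene-window
containment use closed-interval intersection (any overlap counts).
Candidate windows are ±250 kb around each QTN, clipped to the chromosome.
Variant annotation assigns one primary category per variant with priority
exon > splice-site (2 bp at each intron end) > intron > upstream-2kb >
downstream-2kb > intergenic, strand-aware for the flanks; CDS SNP effects
compare codons under the standard genetic code (reverse-complemented for
minus-strand genes), CDS indels are frameshift iff |Δlen| mod 3 ≠ 0.
Variants whose stated reference allele disagrees with the genome are
flagged and excluded from effect calls.

## Expression

Technical replicates are averaged per (sample, gene); ΔCt = Ct_target −
Ct_reference per sample; ΔΔCt subtracts the calibrator group's mean ΔCt;
rq = 2^−ΔΔCt with amplification efficiency fixed at 2.  The calibrator
defaults to the lowest-count phenotype group.  Group dispersion (SD) is
computed over biological samples.  Group comparison: one-way ANOVA and
Tukey HSD; the compact-letter display assigns one letter per maximal
clique of the "not significantly different" graph, ordered by descending
group mean, so two groups share a letter iff their Tukey-adjusted p ≥ α.

## Pipeline

Stages exchange plain files (VCF v4.2 with GT only, GFF3, FASTA, TSV,
JSON) inside one working directory, so each stage is independently
runnable; a manifest records parameters and SHA-256 hashes of every
output, and identical configuration + seed reproduces identical hashes.
Configuration is validated strictly (unknown keys rejected, numeric
bounds checked).

## Problem sizes used in the shipped studies

Model-selection consistency: 100 F2 replicates of n = 400 at d/σ = 2.5.
Heritability recovery: 20 replicates of n = 1000 at a 90 % between-class
share.  Association calibration: 5 panels × 5000 null markers, n = 120,
weak structure (F_ST = 0.05) with Q/K supplied.  Admixture K recovery:
10 two-subpopulation panels (F_ST = 0.3, 100 × 500).  These sizes are the
package's chosen experiment scale; the same routines accept larger inputs
unchanged.

## Known limitations

* The mixture likelihood ignores the discreteness of counts (by design,
  matching the classical framework); diagnostics compensate via the
  randomized PIT.
* No multi-generation joint likelihood (P1/P2/F1/B1/B2) and no
  three-major-gene models (registry hooks only).
* Admixture CV error is a heuristic model-selection criterion; with weak
  differentiation it can prefer smaller K.
* No phasing or haplotype-block partitioning; composite r² stands in for
  haplotype LD.
* Single-marker association only (no multi-locus models, no permutation
  thresholds); additive dosage coding without a dominance term.
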