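# Methods

This note records the models implemented by `sorgwue`, the defaults of
the synthetic generator, the numerical choices, and what passing tests
do and do not establish about real data.

## Anatomical traits

Stomatal density is the mean count over fields of view divided by the
field-of-view area (default 0.59 mm²).  Stomatal size and maximum pore
area use the rectangular approximation appropriate for grass stomata
(SS = SL × SCW, PA_max = PL × GCW).  Because 4–5 stomata are scored per
impression, per-record SS/PA_max are the **mean of per-stoma products**,
the unbiased estimator of mean area; multiplying means of the dimensions
instead is available behind `product_of_means=True` for comparison with
sources that aggregated the other way.  The anatomical maximum
conductance

g_sw.max = d · SD · PA_max / [ v · ( l + (π/2)·√(PA_max/π) ) ],
l = GCW/2,

is computed after internal conversion to SI (SD ×10⁶ → m⁻², PA_max
×10⁻¹² → m², lengths ×10⁻⁶ → m); the public API keeps field units
(mm⁻², μm², mol m⁻² s⁻¹).  π is used at full float precision; a config
switch (`PhysicalConstants(pi_truncated=True)`) reproduces calculations
done with π = 3.1415.  Totals over surfaces are sums (SD, SPALA,
g_sw.max) or arithmetic means (SS, PA_max); aggregation refuses to run
with a missing surface rather than silently falling back.

## Field mixed model

Plot values are modeled as
`trait ~ row + column + AveT + AveH + (1 | accession)` with REML.  Row
and column enter as **categorical** fixed effects by default (absorbing
arbitrary spatial gradients; a numeric-gradient option exists).  Aliased
design columns are dropped with a warning — field layouts routinely
alias — and an AIC utility (ML fits, since REML likelihoods are not
comparable across fixed-effect sets) compares the ±weather-covariate
variants.

Because the only random term is the accession intercept, the covariance
is block diagonal (H_i = I + γJ, γ = σ²_a/σ²_e), and REML reduces to a
one-dimensional profile over log γ, solved by bounded scalar
minimization to 1e-8 on log γ over log γ ∈ [−25, 25].  Each profile
evaluation whitens the data explicitly (H⁻¹/² per group) and solves OLS
by SVD; this matters in the γ → ∞ limit, where between-group design
columns are annihilated and normal equations become numerically
singular.  A boundary estimate (σ²_a → 0) is detected by comparing the
criterion at the lower bound with the interior optimum and is flagged,
not raised.  BLUPs are shrunken group residual sums,
u_i = γ S_i / (1 + γ n_i).

Predictions default to fixed effects at reference covariates (design
means) plus BLUP.  An `observed` mode evaluates each accession's own
mean design row instead; this is the mode that reproduces accession
values exactly in the noiseless limit, because batch-constant
covariates (AveT/AveH are shared by all accessions phenotyped in a
batch) are partially confounded with genetic values and a reference
evaluation cannot undo that confounding.  The chosen mode is logged.

## Association scan

MAF is computed from non-missing dosages and markers **strictly below**
the cutoff (default 3%) are removed; a marker exactly at the cutoff is
retained.  Genotype PCs come from the SVD of the column-centered,
mean-imputed dosage matrix, with each component's sign fixed so its
largest-magnitude loading is positive.  The scan itself is OLS of the
adjusted trait on (intercept, k PCs, dosage), computed by residualizing
phenotype and dosages against the covariates once (Frisch–Waugh —
numerically identical to per-marker joint OLS), with two-sided p from
the t distribution on n−k−2 df.  Zero-variance markers return β = 0,
p = 1 and are flagged.  Missing dosages are mean-imputed per marker at
scan time only; the genotype matrix preserves missingness.

Multi-stage scan algorithms (FarmCPU and kin) are deliberately not
reimplemented; the substitution is noted in every results header.
Kinship-aware mixed-model scanning is a non-goal.  Candidate windows
extend ±75 kb around a significant marker with **inclusive** overlap at
the boundary (a gene touching the window edge counts); an unknown
chromosome yields an empty list with a warning rather than an error.

## Haplotype classes

Accessions homozygous at all focal loci receive the concatenated
ref/alt base string; heterozygous or missing accessions are excluded
with a logged count (how such accessions should be handled is genuinely
underdetermined — exclusion is the least-assumption choice and is never
silent).  Classes are ordered by ascending alternative-allele count,
ties broken by descending frequency, which reproduces the
all-reference-first … all-alternative-last layout without hard-coding;
an explicit anchor ordering (`FOCAL_HAPLOTYPE_ORDER`) pins the exact
layout for the chromosome-1 focal block.  Group comparisons use a
one-way ANOVA and Tukey HSD on the studentized-range distribution with
the Tukey–Kramer harmonic-mean SE (haplotype classes are strongly
unbalanced); letters come from the standard insert-and-absorb
compact-letter algorithm, so two classes share a letter iff their
adjusted p ≥ α.

## Gas exchange and the BWB model

The ball index is A_n·H_s/C_s with H_s a **fraction** in (0, 1];
passing percent RH raises an explicit unit error, and the CSV reader
converts percent columns at read time.  Fits are OLS of g_sw on the
ball index per curve (one accession × treatment × replicate, ≥3 points,
g₀ unconstrained with negative intercepts flagged); slopes are compared
at the replicate level (per-accession t-tests; overall two-way
fixed-effects ANOVA with type-I sums of squares, appropriate for the
balanced design, computed on available cells with a warning otherwise).
A pooled reporting mode replicate-averages per accession × PPFD first
and fits one regression per regime (8 accessions × 11 levels = 88
points per regime under the default panel).  Curve-level iWUE is the
mean of per-record A_n/g_sw across the 11 points.

## Synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Genotypes** — 360 inbred accessions (dosages {0, 2}; readers still
  accept 1), 5,000 markers over 10 chromosomes by default, alt-allele
  frequencies uniform on [0.05, 0.5].  The 3 causal SNPs sit at their
  real chromosome-1 coordinates with alleles C/T, C/T, G/A; loci 2 and 3
  copy locus 1's allele with probability ρ (default 0.4) — a simple,
  seedable LD mechanism (no coalescent machinery; correlation between
  loci 2 and 3 is ≈ ρ²).
* **Field phenotypes** — 3 plots per accession (three plants per
  accession are sampled for trait measurement), randomized onto a
  near-square row × column grid; per-trait row/column effects, batch
  weather covariates (4 batches; AveT 22–28 °C, AveH 58–71%), an
  accession random intercept and residual noise.  Causal effects per
  alt allele: SD_total −6 mm⁻², A_n −0.9 μmol m⁻² s⁻¹, g_sw −0.012
  mol m⁻² s⁻¹, iWUE +4 μmol mol⁻¹ — the directions the haplotype
  analysis encodes (alternative alleles trade assimilation for
  efficiency), at magnitudes detectable but not dominant.  Variance
  components (e.g. A_n: σ²_a = 6.25, σ²_e = 4) are order-of-magnitude
  choices for a moderately heritable gas-exchange trait; within-
  accession measurement error magnitudes are not reported for the real
  panel, so these are exposed in config, not calibrated values.
* **Impressions** — counts are Poisson(density × 0.59 mm²) per field of
  view (2 fields, 3 plants); abaxial density exceeds adaxial by the
  factor 1.255, dimensions by factors 1.094/1.124/1.089/1.030
  (SL/SCW/PL/GCW).  Dimensions are lognormal (CV 8%) around means
  SL 35, SCW 22, PL 17, GCW 5.5 μm — typical dumbbell-shaped C4 grass
  stomata — scaled by an accession-level multiplier correlated with
  density at r = −0.3 (the density–size trade-off).
* **Light curves** — A_n(Q) follows a non-rectangular hyperbola
  (φ = 0.06, θ = 0.7, R_d = 1.5; A_max 35 WW / 18 WS).  This functional
  form is a standard stand-in for measured curves, not a claim about
  the underlying physiology.  g_sw is generated from the BWB relation
  with class-dependent slopes (WW: 6.5…5.7 for classes 1–5, 4.2…3.8
  for 6–8; WS: classes 1–5 drop to 3.6…3.2, classes 6–8 unchanged),
  g₀ = 0.04/0.03, noise σ = 0.02 mol m⁻² s⁻¹, and truncation at 0.005
  to avoid non-physical values.  H_s = 0.60, C_s = 390 μmol mol⁻¹,
  constant per curve.

One master seed drives everything; the four sub-generators (genotypes,
field, impressions, gas exchange) draw from independent spawned child
streams, so stages can be regenerated in isolation and identical seeds
give byte-identical pipeline outputs.

**What the generator does not emulate:** realistic LD decay and
population structure (beyond an optional two-cluster test fixture),
genotype-by-environment interaction other than the WW/WS slope
contrast, spatial autocorrelation beyond additive row/column effects,
and measurement drift within a day.  Passing tests therefore
demonstrate that the estimators recover the truth under their assumed
data-generating process — not that the assumptions hold in any
particular field trial.

## Multivariate statistics

CV = 100·SD/mean (flagged undefined at mean 0); skewness is the
adjusted Fisher–Pearson estimator G1 = √(n(n−1))/(n−2) · m₃/m₂^{3/2}.
Correlations are Pearson on pairwise-complete cases with t-distribution
p-values; constant columns flag their pairs as undefined.  Trait PCA is
the eigen-decomposition of the correlation matrix (complete cases,
deterministic sign convention).  Trait clustering — the method behind
published trait groupings is typically unstated — defaults to Ward
hierarchical clustering on loadings scaled by PC standard deviations,
cut at k (default 3), with k-means reachable via config; Ward was
chosen for determinism.

## Problem sizes used by the acceptance script

Bonferroni bar at M = 234,264; haplotype enumeration on a 360-accession
simulated panel; 8 accessions × 3 replicates × 2 regimes for curve
bookkeeping and the interaction rate (20 replicates); 1,000 random
anatomies for the conductance oracle; 200 noisy curves for slope
recovery; 50 replicates of 360 accessions × 3 plots for REML recovery;
10 × 2,000 markers pooled for null calibration and 20 replicates for
causal-marker power.  These sizes make every quantity stable to well
within its tolerance while keeping the full script under a minute.

## Known limitations

* The scan is single-marker OLS with PC covariates: with strong kinship
  structure it will be miscalibrated where a mixed-model scan would not
  be; the synthetic panel has no such structure by default.
* The REML fit handles exactly one random intercept; multiple random
  effects and spatial covariance models are out of scope.
* VCF support is GT-only, biallelic SNPs, uncompressed; no BCF or
  phased haplotypes.  The dosage-CSV dialect carries no ref/alt
  alleles (defaults A/T) and is intended for synthetic fixtures.
* Compact letters are computed at a single family-wise α; no
  multiple-trait correction is applied across traits.
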