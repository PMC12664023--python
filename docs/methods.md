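# Methods

## Trait model and transformation

The phenotype is a bounded continuous severity score on [0, 10]
(tagged visual analogue scale from radiographs), with a large point
mass near zero and a long right tail.  All variance-component and
association models assume Gaussian residuals, so the package works on
the shifted natural log

    logKBF = ln(score + 0.05),

where the offset 0.05 — the smallest observed nonzero score — makes
zeros transformable.  The transform is strictly increasing and exactly
inverted by `exp(x) − 0.05`; both scales are fitted for variance
components (the observed scale for comparability, the log scale as the
primary analysis), while association scans use the log scale only.
Descriptive statistics use the sample SD (n−1), the near-universal
convention for summary tables.

## Genomic relationship matrix

VanRaden method 1: `G = ZZ′ / Σᵢ 2pᵢ(1−pᵢ)`, with `Z` the matrix of
allele counts (0/1/2) centered by `2pᵢ` and `pᵢ` estimated from
non-missing calls of the analyzed sample itself.  Missing dosages are
mean-imputed to `2pᵢ` before centering — the standard choice, which
also preserves the zero-column-sum identity of `Z` and hence a grand
sum of exactly zero for `G`.  Monomorphic SNPs drop out of both the
numerator and the denominator.  In an F1 cross the denominator (the
HWE-expected heterozygosity) exceeds the realized SNP variance, so
mean self-relationships sit below 1; this is expected and no HWE
rescaling is applied.  Population structure is summarized by the top
principal components of `G` (variance fraction = eigenvalue / trace),
computed by full symmetric eigendecomposition — exact and cheap at
n ≈ 1,000.

## REML variance components

Single-GRM animal model `y = μ + Xb + u + e`, `u ~ N(0, G σᵤ²)`,
`e ~ N(0, I σₑ²)`, with pen and rearing pen as dummy-coded fixed
effects (redundant columns dropped by a rank-revealing pass; recording
date is deliberately not fitted because it is almost entirely
confounded with pen).  The fit rotates into the eigenbasis of `G`,
where the covariance is diagonal in the variance ratio
λ = σᵤ²/σₑ²; σₑ² has a closed form at each λ, leaving a 1-D bounded
optimization of the profile REML log-likelihood over log λ
(λ ∈ [e⁻¹², e¹²], convergence 1e−9), with an explicit comparison
against the λ = 0 boundary so `h² → 0` is representable.  Standard
errors come from the inverse average-information matrix at the
optimum; the SE of `h² = σᵤ²/(σᵤ²+σₑ²)` uses the first-order delta
method.  A non-PSD input matrix is shifted by its smallest eigenvalue
with a warning.

The two-GRM partition model `y = μ + Xb + u₁ + u₀ + e` with
`u₁ ~ N(0, G₁σᵤ₁²)` (SNPs in significant/suggestive haplotype blocks)
and `u₀ ~ N(0, G₀σᵤ₀²)` (the rest of the genome) is fitted by AI-REML:
Newton steps on (σᵤ₁², σᵤ₀², σₑ²) using the average-information
matrix, falling back to an EM step whenever an AI update would leave
the parameter space, with components floored at 1e−8 · var(y)
(projection at the boundary rather than log-parameterization, so
boundary estimates remain representable).  Convergence: relative
parameter change or log-likelihood change below 1e−8, at most 200
iterations; non-convergence is flagged, never raised.  The quantity of
interest is the partition proportion `σᵤ₁²/(σᵤ₁² + σᵤ₀²)` with a
delta-method SE from the inverse AI matrix.  Identical block and rest
GRMs make the model non-identifiable and are rejected.

## Association scan and inflation control

Each SNP is tested with the genotypic OLS model
`y = μ + X_PC b_PC + zᵢaᵢ + wᵢdᵢ + e`: `zᵢ` the centered allele count,
`wᵢ` the heterozygosity indicator, and `X_PC` the smallest leading set
of principal components of the centered pen × rearing-pen dummy design
explaining > 99% of its variation.  Additive and dominance effects get
marginal two-sided Wald t-tests within the joint model (a single β and
p per channel, with dominance reported separately).  Individuals with
a missing call are deleted casewise per SNP; with only two genotype
classes present the dominance column is collinear and is dropped, its
p-value reported missing.  SNPs with fewer than 10 calls, one genotype
class, or residual collinearity are flagged, never scored.  A
mixed-model (GRM random effect) scan is deliberately not used: in this
design stratification is limited (leading GRM PCs explain only a few
percent of relationship variation) and the pipeline instead applies an
empirical post-hoc correction — observed −log₁₀(p) below 3 are
regressed through the origin on expected quantiles
`−log₁₀((i−0.5)/m)` (standard unbiased QQ positions), and all observed
values are divided by the slope, separately for the additive and
dominance channels.  Division by a positive constant preserves
ranking; an intercept option exists but the default is through-origin
because the null expectation is the identity line.

Independent tests are counted by greedy LD pruning (500 kb window,
10-retained-SNP step, r² > 0.2 on dosages — composite LD, matching
unphased-data practice).  Within a window the lower-MAF member of the
worst pair is removed (ties: later map position), the window advances
ten retained SNPs, and passes repeat until stable; a final step-1
sweep guarantees the audit property that no retained pair within the
window span exceeds the threshold.  Significance thresholds are then
0.05/m (genome-wide) and 0.10/m (suggestive), applied to the
*corrected* p-values.

## Haplotype blocks

Two-SNP haplotype frequencies come from an EM over the
double-heterozygote phase ambiguity (all other genotype pairs count
haplotypes directly; tolerance 1e−8, max 1,000 iterations).  D′ is
|D|/D_max.  Its confidence interval profiles the multinomial
likelihood of the 3×3 genotype table over a 101-point grid of
|D′| ∈ [0, 1] (allele frequencies held at their estimates, D signed as
the point estimate), normalizes the grid to unit mass, and takes the
central 90% of the cumulative curve — the Haploview-style
construction, chosen because block definitions in this field name only
the CI bounds, not the algorithm.  A pair is "strong LD" iff
CI_low ≥ 0.60 and CI_high ≥ 0.90.  A candidate block is a contiguous
map run spanning ≤ 5,000 kb whose outermost pair is strong; it is
accepted when ≥ 95% of its informative pairs are strong (the Gabriel
default, exposed in config), and overlapping candidates resolve
longest-span-first.  Significant/suggestive SNPs map into blocks by
position; hits outside any block become width-1 singleton intervals.
Labels are `chrom_k` in map order per chromosome.

## Annotation

Features from a local BED/GFF3 table are reported for a block when
they intersect the block extended by the flank (default 50 kb), with a
strict boundary: the gap must be < 50,000 bp, so a gene ending exactly
50 kb away is excluded.  Distances are positional (upstream =
lower coordinates); feature strand is ignored because the criterion is
about physical proximity, not transcription, and gene-body borders
(not TSS) anchor the distance.  Single-bp touching counts as overlap.
Coordinates are 1-based inclusive everywhere in memory; BED's 0-based
half-open convention is converted at the I/O boundary only.

## Synthetic cohorts

The generator emulates the target study design: F1 hens from two
purebred founder lines, paternal half-sib families, cross-classified
housing, and a bounded right-skewed score.

* **Defaults** (all overridable): 25 sires × 42 dams × 1 offspring
  (1,050 hens, half sibs only — full-sib pairs are essentially absent
  in the emulated cohort), 10 chromosomes × 500 SNPs of 100 cM each
  (the scale the validation suites use; larger panels are a config
  change), 5 pens × 8 rearing pens assigned stratified by sire,
  pen-effect SD 0.25, liability mean −0.58 and SD 1.3 (matching the
  observed log-score moments), log-scale heritability 0.22, 20 QTL
  with additive-effect SD 0.15 and dominance on half of them.
* **Founder lines**: per-SNP allele frequencies drawn per line from
  Beta(2, 2); haplotypes drawn SNP-independently within line.  Sample
  LD that decays with genetic distance arises from co-inheritance of
  founder haplotype segments within the finite sire set, not from
  ancestral LD — sufficient to exercise pruning and block detection
  without a coalescent engine.
* **Meiosis**: Haldane model (no interference); adjacent-SNP
  recombination fractions `c = (1 − e^{−2d})/2` for map distance d in
  Morgans, implemented as a first-order Markov walk over the two
  parental strands.  Physical positions place 1 cM ≈ 300 kb.
* **Trait**: Gaussian liability = mean + pen + rearing pen + QTL
  (additive + dominance) + polygenic background over ≤ 1,000 SNPs,
  with the realized genetic values rescaled so the genetic share of
  the non-fixed variance equals the configured heritability exactly;
  residuals make up the rest.  The observed score is
  `clamp(exp(liability) − 0.05, 0, 10)`, so the shifted-log transform
  recovers the liability exactly wherever the clamp is inactive; the
  clamp touches roughly 4–5% of individuals at the default moments,
  mildly attenuating estimated heritability on both scales — the same
  censoring a real bounded score imposes.
* **Determinism**: a root RNG keyed by the seed spawns one child
  stream per chromosome plus one for the trait, so results are
  reproducible and chromosome streams are parallel-safe.

What the generator does **not** emulate: ancestral within-line LD,
mutation/selection, multi-generation pedigrees, sex chromosomes,
genotyping error, and family-size imbalance (balanced by default,
settable via `family_sizes`).  Passing tests therefore demonstrate
correctness of the estimators under a known half-sib architecture, not
performance under every feature of real SNP-chip data.

## Validation sizes and numerical choices

Parameter-recovery suites run 20 replicate cohorts at n ≈ 1,050 with
5,000 SNPs — large enough that the REML sampling SD of h² (~0.06)
averages to well within the 0.05 acceptance band over 20 replicates.
The REML grid oracle uses n = 50 with a 200-point log-spaced ratio
grid; type-I-error calibration uses 10,000 null SNPs at n = 500;
block recovery uses 3 perfectly coupled 4-SNP blocks at n = 250.
Key tolerances: EM convergence 1e−8; profile-REML bracket
[e⁻¹², e¹²] with 1e−9 x-tolerance; GRM symmetry checked to 1e−8;
PCA eigenvalues clipped at 0 to absorb roundoff.

Counted-allele orientation follows allele1 of the PED/MAP pair as
encountered; MAF is computed downstream, so r², the GRM and p-values
are orientation-invariant (effect signs flip with orientation).  The
MAP files the package writes carry two extra allele columns so round
trips preserve orientation even when a SNP's first call is homozygous
for the other allele; plain 4-column MAPs are read with the
first-encountered convention.

## Known limitations

* The inflation slope is a global correction; it cannot repair
  locus-specific confounding.
* The block detector implements the published Gabriel-style criterion
  (outermost-pair strong, 95% of pairs strong) without the
  recombination-evidence sub-rules of PLINK's `--blocks`; block
  boundaries can differ from PLINK's on borderline data.
* Per-individual call-rate QC is not applied (only per-SNP), matching
  the intended workflow where individuals are dropped earlier for
  missing housing or genotype records.
* The two-GRM AI-REML needs a few hundred iterations at worst near
  boundaries; estimates at the floor have asymmetric sampling
  distributions that the symmetric SEs only approximate.
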