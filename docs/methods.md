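# Methods

This note documents the statistical models behind `magpop`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want recorded.

## Data model

The unit of observation is a *population pool*: all metagenomic reads from
one station/depth recruited against one reference genome.  Per reference
position the pool contributes nucleotide counts (`A:T:C:G:N:del`), held in
an `AlleleCountTable` and serialised in the PoPoolation2 sync dialect.
Analysis is bi-allelic throughout: the alternative allele at a site is the
most frequent non-reference base over all pools, ties broken in the fixed
order A < C < G < T; residual third/fourth alleles are ignored (counted and
logged).  Internal coordinates are 0-based half-open; sync, VCF and GFF3
serialise 1-based per their standards.

## Recruitment QC

A sample must pass, in order: an 80% read-identity filter, a mean vertical
coverage of at least 4× (averaged over *all* reference positions, zeros
included — the conservative "depth over genome" convention), a coverage
breadth of at least 80% of positions with depth ≥ 1, a unimodal depth
distribution, and finally a 97% identity filter for the reads that enter
variant calling.  Coverage checks default to the 80%-filtered reads; a
switch moves them after the 97% stage.  Read identity is
100 × (alignment columns − edit distance) / alignment columns, with gap
columns in the denominator.

Unimodality is operationalised as Hartigan's dip statistic with a bootstrap
p-value against uniform samples of the same size (the least-favourable
unimodal null); a sample fails at p < 0.05.  Two numerical details matter:

* depth values are **counts**; the stair-step empirical CDF of tied values
  inflates the dip, so depths are dithered with U(−½, ½) noise
  (deterministic given the seed) before testing;
* samples larger than 1,000 covered positions are deterministically
  subsampled first — the dip is scale invariant, so this costs only power,
  and it keeps the bootstrap cheap.

The dip implementation is the classical iterative greatest-convex-minorant
/ least-concave-majorant algorithm, written here because no installed
library provides it; the test suite pins it against a brute-force oracle
that solves the defining minimisation (closest unimodal CDF in sup-norm)
by linear-programming feasibility plus bisection on small samples.

## SNV calling and the variant landscape

A site is an SNV when the pooled minor-allele count is ≥ 2 and *every*
admitted pool's coverage lies in [4, 200] ("min-covered-fraction 1":
a site missing in any pool is excluded genome-wide, so densities are
comparable across samples).  SNV density is reported per covered position —
positions passing the same coverage window — rather than per assembled
base, so assembly gaps do not dilute it.  Context classification assigns
each position to exactly one of coding / UTR / intron / intergenic with
precedence coding > UTR > intron on overlap.  Effects substitute the
alternative base into its codon (reverse-complemented on minus-strand
genes) and translate with the standard code; stop-gain is nonsense,
synonymous is silent, everything else — including stop-loss — is counted
as missense so that the three-class summary stays exhaustive.

## Fixation index

The default per-locus estimator is frequency-based Nei-style
`F_ST = (H_T − H_S)/H_T` (formulas in the README), computed per site
(window and step of one) from pool frequencies alt/(ref+alt).  Sites with
`H_T = 0` carry no information about differentiation and are suppressed,
not scored zero.  Medians across loci, not means, summarise pool pairs:
the per-locus distribution is strongly right-skewed and the median is
robust to the outlier tail that the selection scans go looking for.
Qualitative labels follow the conventional bands: < 0.05 low, 0.05–0.15
moderate-to-high, ≥ 0.15 great.

Two variants are available behind flags: a Hudson-style estimator
(`1 − H_w/H_b`), whose ratio of expectations is unbiased for the island
inbreeding parameter, and a count-corrected form that applies the
`n/(n−1)` small-sample correction with `n` the effective number of
sampled chromosomes (capped by pool size, default 500).  The
frequency-only form stays the default because every downstream statistic
(LK, BAF scans) is built on the same frequency scale.

Region-level differentiation collects, for each region pair, the median
pairwise F_ST of all sample pairs spanning the two regions — across
genomes when several are analysed — and reports their mean.

## Selection scans

**Lewontin–Krakauer.**  `LK_ℓ = (n−1) F_ST,ℓ / mean(F_ST)` with `F_ST,ℓ`
the joint n-pool estimator.  Under neutral drift in a single species LK is
asymptotically χ²(n−1); the normalisation by the mean makes the statistic
invariant to constant rescaling of F_ST, so the choice of estimator scale
cancels.  The classical definition normalises by the mean (not the
median); that convention is used here.  p-values are upper-tail χ²,
q-values Benjamini–Hochberg, candidates at q < 0.15.

**PCA outlier scan** (pool-seq mode).  Loci with minor allele frequency of
the across-pool mean BAF below 0.05 are removed; each locus is centred by
its mean BAF and scaled by the binomial standard deviation
`sqrt(p̄(1−p̄))` (not the empirical SD, which would normalise away exactly
the excess dispersion the scan must detect); the pool × locus matrix is
decomposed by SVD and each locus summarised by its loadings on the top K
axes (K defaults to pools − 1, the small-pool regime of 3–9 samples; a
smaller K can be passed).  The robust Mahalanobis distance of the loading
vectors uses the minimum covariance determinant with a fixed seed so that
the outliers do not inflate their own null; distances are divided by the
genomic inflation factor (median D² over the χ²_K median) before χ²_K tail
probabilities, then Benjamini–Hochberg.  BH is used rather than a π₀
estimator because it is deterministic and dependency-free; with π₀ ≤ 1 it
is only conservative.  Aberrant pools (score beyond 6 median absolute
deviations on any axis) can be flagged and excluded before scanning to
avoid false-positive inflation.

## Isolation by environment

Environmental preprocessing drops ammonium, merges nitrate + nitrite into
one variable, and z-scores; collinearity is *reported* (Spearman p < 0.01
pairs, variance inflation factors ≥ 10) but flagged variables are
retained — with a handful of stations, pruning would be as arbitrary as
keeping them, and the diagnostics travel with the result.

The response is the vectorised upper triangle of the median pairwise F_ST
matrix (m = n(n−1)/2 observations).  For each variable the per-pair
distances form the pair features `f`; the default covariance kernel
between pairs is a Gaussian kernel `exp(−(f_a−f_b)²/2h²)` with bandwidth
`h = median(|f_a − f_b|)/4`, trace-normalised to m.  This encodes
"pairs at similar environmental separation have correlated
differentiation" — a smooth, not-necessarily-linear isolation-by-
environment response.  The linear analogue (Gower double-centring of the
pair-level squared differences, a rank-one kernel along the centred
distance vector) is available as `pair_kernel(method="gower")`, but it is
not the default for an estimation reason: a rank-one kernel gives the
variance component a single chi-square degree of freedom, and the ratio
estimate of its variance *share* then carries a Jensen bias of roughly
−0.2 at a true share of 0.5.  The RBF kernel's higher effective rank
(~7 at 12 samples) concentrates the component estimate enough that
simulated shares of 0.2/0.5/0.8 are recovered with mean error below 0.05.

Components for all kernels plus an identity residual are estimated by
REML with the damped fixed-point (EM-type) iteration
`σ²_k ← σ²_k · (yᵀPK_kPy)/tr(PK_k)` and clipping at zero; an intercept is
the only fixed effect.  With fewer than six pairs the model drops to a
Haseman–Elston-style method-of-moments least squares fit.  Reported
proportions are `σ²_k / Σσ²`; the share of raw response variance not
reproduced by the fitted covariance is reported separately as the fixed
unexplained part.  A residual share above 0.3 triggers a diagnostics
warning — with ≤ 10 pairs and five or more kernels the model is weakly
identified and results should be read qualitatively.  Identical kernels
alias: their individual split is arbitrary but their sum is stable (tested).

Mantel tests verify each variable independently: Pearson correlation of
the matrix triangles, one-sided (the isolation-by-X alternative), p-value
by joint row/column permutation with the +1 correction, 9,999 permutations
by default.  Note that the minimal attainable p equals 1/(n_perm+1) only
for matrices without non-trivial distance-preserving relabellings.

## Synthetic-data generator

`simulate_metapopulation` draws, per locus, an ancestral frequency uniform
on `ancestral_maf_range` (default 0.1–0.9), then per pool a frequency from
the Balding–Nichols Beta construction — mean equal to the ancestral
frequency, shape scaled by `(1−θ)/θ` — and finally binomial read counts at
a negative-binomial coverage (default mean 100×, dispersion 0.05; the
Poisson limit as dispersion → 0).  Planted outlier loci redraw their pool
frequencies with an elevated θ.

**Calibration of `fst_target`.**  The parameter is defined on the
observable scale: it is the expected value of the default per-locus
estimator for a pool pair at the nominal coverage.  The per-locus ratio
statistic is not an unbiased estimator of θ itself — its ratio of
expectations is θ/(2−θ), and Jensen curvature shifts the mean of ratios
further — so the generator inverts the mapping θ ↦ E[per-locus F_ST]
numerically (fixed-seed internal Monte-Carlo of 60,000 locus pairs,
bisection to 10⁻⁵).  The inversion is cached and independent of the user
seed, so datasets remain bit-reproducible.  Downstream, the *mean*
per-locus F_ST recovers `fst_target`; the *median* sits lower, as it does
on real data.

**Environment linkage.**  The realised genetic distances between pools are
embedded in one dimension by classical multidimensional scaling; a linked
variable mixes that embedding with independent noise, the mixing weight
solved by bisection so that squared pairwise environmental distances reach
the requested R² against genetic distance.  Under a pure island model all
pool pairs are nearly exchangeable, so the 1-D embedding caps the
achievable linkage (around 0.5 at eight pools); the generator therefore
records the *realised* fraction as truth.  Environmental variables are
reported in plausible Arctic field units (temperature ~2 ± 2 °C, iron
~0.4 µM, silicate ~8 µM, ...), nonnegative except temperature.

**Toy genomes.**  `simulate_annotation` lays out stranded genes (5′UTR,
2–4 exons with introns, 3′UTR, intergenic gaps) on multiple contigs, CDS
always complete (ATG … stop, length divisible by 3, no internal stops) so
effect classification is well defined, and emits a mutation list whose
transition:transversion ratio and effect-class proportions converge to the
requested values: each mutation first draws its context, transition state
and (if coding) effect class from the requested mixes, then
rejection-samples a position/alternative satisfying them.  Every mutation
carries its intended class, so classifier recovery can be asserted
*exactly*, not statistically.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage between loci (all loci independent),
sequencing error and mapping bias, indels and multi-allelic sites,
reference bias in recruitment, spatially structured (non-island)
demography, and temporal autocorrelation of environmental fields.  The
island model here is a test harness, not an inference about any organism's
demography.

## Problem sizes and seeds

The statistical acceptance tests run, per check: 5,000 loci × 4 pools for
estimator recovery; 20,000 loci for the LK null (Kolmogorov–Smirnov D
against χ²₃ below 0.05, type-I error 0.05 ± 0.02); 10,000 loci with 50
planted outliers for scan power (≥ 80% recovered, ≤ 2% of neutral loci
flagged); 50 replicates per share for variance-partition recovery at 12
samples; 1,000 trials × 199 permutations for Mantel calibration; 3,000
truth-labelled mutations for landscape recovery.  All stochastic tests fix
their seeds; every generator and scan is deterministic given its
configuration and seed.

## Known limitations

* The PCA scan's χ²_K null for Mahalanobis distances is asymptotic in the
  number of pools; with 3–4 pools the genomic-inflation correction carries
  most of the calibration burden.
* The count-corrected F_ST variant approximates the effective number of
  chromosomes by min(coverage, pool size) per pool; it is a pragmatic
  correction, not an exact pool-seq likelihood.
* Variance partitioning with many collinear kernels on few pairs is
  honestly under-identified; the residual-share warning and the Mantel
  verification exist precisely because single-variable attributions at
  this sample size are fragile.
* The dip-based unimodality verdict tests the depth *distribution*; a
  mixture of genomes with coincidentally similar coverage means passes it.
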