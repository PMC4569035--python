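# Methods

`msatld` estimates multi-allelic linkage disequilibrium (LD) from unphased
diploid genotype panels and analyses its structure the way long-term
individual-based studies do: background LD, decay with map distance,
sample-size bias, interannual variation at fixed sample size, and the link
to relatedness.  This note records the models, the numerical choices, and
what the bundled simulator does and does not emulate.

## Haplotype frequencies by gene-counting EM

For a marker pair, individuals typed at both loci ("pairwise-complete
deletion"; no imputation) contribute genotype pairs.  Single or double
homozygotes and single heterozygotes have determined gametic phase; a
double heterozygote (i1/i2, j1/j2) is split between its two phase
decompositions (i1j1, i2j2) and (i1j2, i2j1) in proportion
x(i1,j1)x(i2,j2) : x(i1,j2)x(i2,j1) under the current frequency table x
(E-step); expected haplotype counts are renormalized over 2N (M-step).

* Initialization: the independence table p_i q_j (gene-count marginals).
  Ties between equivalent phase decompositions then resolve symmetrically.
* Convergence: max |Δx| < 1e-8 (default), capped at 1000 iterations;
  non-convergence is flagged, never silent.  The log-likelihood trace is
  monotone non-decreasing (tested), and the final table satisfies the
  marginal constraints exactly by construction of the M-step.
* Alleles unobserved in the pairwise-complete subset are dropped, so the
  per-pair allele counts k, m are sample quantities.
* A sample consisting only of double heterozygotes does not identify the
  phase split (any x with x11x22 + x12x21 fixed is a maximizer); such
  tables are flagged `ambiguous`.  A `restarts` option (random Dirichlet
  starts, best likelihood kept) is available for degenerate cases.

## LD statistics

With D_ij = x_ij − p_i q_j:

* **D′** = Σ_ij p_i q_j |D_ij / D_max(i,j)|, where D_max is
  min(p_i q_j, (1−p_i)(1−q_j)) for negative D_ij and
  min(p_i(1−q_j), (1−p_i)q_j) for positive; the ratio is defined as 0 at
  D_ij = 0 (limit convention).
* **χ′²** = [Σ_ij D_ij²/(p_i q_j)] / (min(k, m) − 1), the classical
  two-locus χ² normalized by 2N(min(k,m)−1).  It reduces to r² for
  biallelic loci (tested against the closed form) and is undefined when
  min(k, m) = 1 (monomorphic; such pairs are excluded).

Both statistics lie in [0, 1] and are invariant to allele relabeling and
to swapping the two loci.  χ′² ≤ D′ is *not* guaranteed and is not
asserted.  Both are upward-biased in small samples; for χ′² the
independence expectation is approximately (k−1)(m−1)/(2N(min(k,m)−1)),
which is what makes background LD at n = 10 several-fold larger than at
n = 200.  This inflation is a feature of the estimators the analysis is
designed to characterize, not a defect to correct.

## Background LD and the half-length

Background LD is the arithmetic mean (and sample SD) of a metric over
nonsyntenic pairs — different chromosomes — only.  Syntenic pairs at
≥ 50 cM enter neither the background nor the decay fit.

Decay with map distance d is modelled over syntenic pairs under 50 cM as

    LD(d) = (b − P3) · exp(−d · ln 2 / P2) + P3

the unique exponential parameterization in which P2 *is* the half-length:
LD(P2) − P3 = (b − P3)/2 exactly.  P3 is fixed at the nonsyntenic mean
before fitting; b (the intercept) and P2 are solved by bounded nonlinear
least squares (`scipy.optimize.curve_fit`, trust-region reflective).  The
intercept is estimated, not constrained to 1: completely linked markers
need not be in complete LD because of historical recombination.  0 cM
pairs are included.  Unweighted least squares is used (replicate distances
receive no special treatment).

* Starting values: b0 = mean LD of pairs under 2 cM (fallback: max
  observed LD), P2 = 10 cM.  Bounds: b ∈ (P3, 1], P2 ∈ (0, 10⁴] cM.
* Standard errors are Jacobian-based asymptotic; their calibration against
  the empirical replicate SD is tested (ratio within [0.8, 1.25] over
  noisy Monte-Carlo fits).
* Identifiability: flat responses raise; fits whose P2 exceeds twice the
  maximum fitted distance are flagged not converged, because a curve that
  never approaches its asymptote inside the 50 cM window does not identify
  a half-length.  Resampling summaries exclude flagged fits and report the
  failure rate.

Mean LD versus sample size n is summarized by the power function
f(n) = c·nʳ, fitted by nonlinear least squares with a log-log start and
r² = 1 − SSres/SStot.

## Subsampling designs

Both designs draw individuals **without replacement** and recompute
everything — allele frequencies, EM haplotype tables, background,
decay fit — from scratch per draw; each replicate's decay fit uses its own
nonsyntenic mean as P3.

* Sample-size curve: sizes 10–200, many replicates per size.
* Yearly cross-sections: a fixed k = 20 per year, 500 replicates by
  default; years with fewer than k individuals are skipped with a warning,
  and a year with exactly k yields identical replicates (there is only one
  possible subsample), reproducing the well-known small-cohort caveat
  mechanically.

A single master seed spawns one substream per (size-or-year, replicate)
via `numpy` SeedSequence, so results are independent of execution order.
Mean relatedness is evaluated on the *same* draws, pairing LD and
relatedness replicates.

## Relatedness

* **Queller–Goodnight**: per locus, with focal alleles (a, b) and partner
  alleles (c, d), num = 0.5(I_ac+I_ad+I_bc+I_bd) − p_a − p_b and
  den = 1 + I_ab − p_a − p_b; the multilocus estimate is the ratio of sums
  over both reference directions and all shared loci (the standard
  weighting; per-locus averaging is not used).  Reference frequencies come
  from the full filtered panel, never from a subsample, and the focal pair
  is not excluded from frequency estimation (the small resulting bias is
  accepted).  The all-pairs implementation reduces every pairwise sum to a
  matrix product over per-allele count vectors and agrees with the
  explicit per-pair loop (tested).  Pairs with a zero summed denominator
  are reported missing.
* **Pedigree**: the additive relationship A (twice the kinship) by the
  tabular method; founders unrelated and non-inbred, unknown parents
  contribute 0.  A is symmetric positive semi-definite (tested by
  eigenvalues on simulated pedigrees).
* Yearly series are compared by Pearson correlation with
  t = r√(n−2)/√(1−r²) on n − 2 degrees of freedom.

## Model selection for syntenic LD

The response is a metric over syntenic pairs under 50 cM; candidate terms
are log intermarker distance, mean expected heterozygosity of the pair,
and chromosome as a factor.  Since 0 cM pairs exist, the log transform
uses ln(d + 0.1 cM); 0.1 cM is below typical microsatellite map
resolution, and the offset is a configuration knob.  Continuous predictors
are standardized on 2 SD; factor indicators (first level dropped) are
centered only, so coefficients are comparable across types.

All 2^T subsets are fitted by OLS (statsmodels), with the Gaussian
log-likelihood at σ̂² = RSS/n and k counting intercept + slopes + σ²
(so a distance+heterozygosity model has k = 4, adding a 26-level
chromosome factor gives k = 29).  Ranking uses
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); Akaike weights are computed over the
full model set, and the Δ < 2 filter is reporting-only.  Exact AICc ties
are broken toward fewer terms.  Exact fits (RSS ≈ 0) are floored at
σ² = 1e−12 and flagged degenerate.

## The simulator

The generator produces inputs with the statistical structure the analysis
assumes: a mapped panel (default 26 chromosomes × 8 microsatellites,
gamma-distributed spacings with mean 15.6 cM and SD 10 cM, 5–15 alleles
per locus from Dirichlet(1) ancestral frequencies), ~2% missingness
(capped at the 15% inclusion threshold), ~20 yearly cross-sections, and a
recorded pedigree.

* Reproduction: the population is wholly replaced every `generation_time`
  years (default 1) and persists in between, so individuals appear in
  several yearly cross-sections.  Age structure and overlapping
  generations are not modelled; the shipped ungulate-like scenarios use a
  generation time of 3 years as a compromise between the species'
  ~6-year generation time and yearly turnover at desk scale.
* Mating: dams uniform among females; sires drawn from the top
  `male_fraction` of males with geometrically decaying weights —
  a polygynous skew in which a minority of males sire most offspring.
* Recombination: crossovers follow the Haldane map function on cM
  distances (c = 0.5(1 − e^(−2d/100)), no interference), implemented as a
  Markov strand switch along each chromosome.
* Admixture: migrant haplotypes come from a source population drifted
  independently from the same ancestral frequencies for G generations
  (G = 20 by default; the real founder/source divergence is unknown, so G
  is a free scenario parameter).
* Mutation is off by default (negligible over ~20 years); a stepwise
  option exists.

Two templates are shipped as YAML: a native population growing ~100→220
then declining to ~60 with no immigration, and a 12-founder population
held near a census of 48 for six decades and then rescued by admixture
pulses totalling 15 migrants across four introductions.  The last two
introductions are 6 and 3 individuals; the first two are not individually
documented, so the package splits the remainder 4 and 2 with the first
pulse largest (it is the one that produces the initial LD spike).

### Scaled study sizes

The full design (208 loci → ~21,500 pairs, 1000 replicates per subsample
size) is far larger than needed to exercise the methods, so the test suite
and the acceptance script run reduced variants chosen so that their
*full-sample* LD summaries sit in the range long-term ungulate panels
report: the stable scenario (4 chromosomes × 12 loci at ~8 cM, N = 220)
yields D′ intercept ≈ 0.79, background ≈ 0.25 and half-length ≈ 12 cM
(χ′²: 0.53 / 0.06 / 7.5 cM); the two demographic templates run on
6 × 6-locus maps.  Replicate counts are 40–500 depending on the check.

### What passing tests do and do not show

The simulator emulates drift, polygyny, bottlenecks, admixture and map
structure, so directional results (background inflation at small n,
half-length depression at small n, the bottleneck-population excess in
background and half-length, the post-pulse LD spike and decay, the
positive yearly relatedness–background-LD association after a rescue) are
qualitative reproductions, not numerical ones.  Features of real data the
generator does not produce: overlapping generations and age structure,
genotyping error and allele binning artifacts, non-random sampling within
years, mutation, selection, and sex chromosomes.

Two scale-dependent observations are worth recording.  The small-sample
*depression* of half-lengths arises from the bounded statistics
compressing against their ceiling when small-n inflation pushes background
toward the intercept; it is strongest for D′ (whose background inflates to
~0.6 at n = 10) and correspondingly weaker for χ′² at this panel size.
And in a long simulated *decline* without immigration, the loss of allelic
diversity shrinks the fixed-k χ′² inflation term over the years, which can
dominate the yearly background series and flip its correlation with rising
relatedness — so the positive relatedness–LD association is asserted for
the bottleneck-then-rescue scenario, where admixture drives both series,
and not for the declining-native one.

## Numerical conventions

* Missing genotypes: both alleles missing; GenePop "0000"/"000000".
  Partial-zero codes are treated as missing (half-calls are not
  representable).
* Filters: loci first (on the pre-filter individual set), then individuals
  (on retained loci), one pass each; both thresholds default to 15%.
  The filter is idempotent.
* D′/χ′² values are clipped into [0, 1] against rounding at the 1e−12
  level; EM tables satisfy Σx = 1 to 1e−9.
* Decay-fit and power-fit failures raise or are flagged, never silently
  interpolated; resampling records them as missing with a reported rate.
* All stochastic entry points take explicit seeds; pipeline reruns with the
  same inputs, config and seed produce byte-identical TSV artifacts
  (checksummed in the run manifest).
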