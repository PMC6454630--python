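# Methods

## Model overview

`methrank` tests, per genomic feature, the null hypothesis that the observed
DNA-methylation discordance between a test and a reference sample is
explained by normal biological, statistical and technical variability.  The
data it consumes are per-GU (150-bp genomic unit) methylation-level
distributions, or the Jensen-Shannon distances (JSD) already computed between
test and reference distributions per GU.  Three layers make up the method:

1. **Discordance statistic.**  For a feature overlapping K data-bearing GUs,
   T = sqrt((1/K) Σ JSD(k)²) with base-2 logarithms, so T ∈ [0, 1].  With a
   uniform phenotype prior, T² equals the average per-GU mutual information
   between methylation level and phenotype (tested to 1e-10 against a direct
   evaluation of the mutual-information sum), and T obeys the triangle
   inequality across phenotypes (property-tested on random instances).

2. **Size-dependent null.**  The null law of T depends on the feature size
   s = log2 K.  It is modeled as logitSST: Y = logistic(μ + σZ) with Z a
   Fernandez–Steel skew-t,

       f(z; ν, τ) = 2/(ν + 1/ν) · [ f_t(z/ν; τ) for z ≥ 0; f_t(νz; τ) for z < 0 ],

   chosen for its closed-form CDF (piecewise in the Student-t CDF, hence an
   exact quantile function) and because ν = 1 recovers the symmetric t.  The
   four curves μ(s), ln σ(s), ln ν(s), ln(τ(s) − 2) are penalized cubic
   B-splines (20 equally spaced interior knots over the observed s range,
   second-order difference penalty) fitted by maximum penalized likelihood to
   the pooled (t, s) observations of all reference/reference comparisons.
   ln(τ − 2) is the link for the tail parameter so that τ > 2 (finite
   variance) is enforced throughout.

3. **Combination and ranking.**  Promoter + body p-values of a gene are
   combined with Fisher's T_pb = −2 ln P_p − 2 ln P_b and referred to the
   empirical CDF of T_pb over all features and all reference/reference pairs
   (pooled; the empirical p-value is floored at 1/(N_r + 1), the resolution
   of an empirical CDF with N_r observations).  Across N_t test/reference
   comparisons, T_mult = −2 Σ ln P⁽ⁿ⁾ is referred to χ²_{2N_t}.  Final lists
   are sorted by combined p; ties break by rank product (geometric mean of
   per-comparison ranks), then lexicographically by feature id; q-values are
   Benjamini–Hochberg.  Rank products are used only for tie-breaking, never
   for significance.

## Fitting algorithm and numerical choices

The distributional regression is fitted by cyclic backfitting: each curve in
turn receives damped penalized-Newton updates (per-observation gradient and
curvature in the linear predictor obtained by central finite differences,
step h = 1e-4; curvatures clipped to [1e-6, 1e8]; step-halving guarantees the
penalized log-likelihood never decreases), cycling until the penalized
log-likelihood changes by less than a relative 1e-6 or 200 cycles are
reached (non-convergence raises an error carrying the last iterate).
Initialization is deterministic: constant curves from moments of the pooled
logit-transformed observations, ν = 1, τ = 10.

Per-curve smoothing parameters are selected by coordinate descent over the
grid {1, 10, …, 1e6}, refitting one curve at a time (warm-started) and
scoring by AIC with that curve's effective degrees of freedom (the trace of
its smoother hat matrix); two passes are used, then a final full backfit.
The grid's upper end matters: the second-order difference penalty leaves
linear coefficient sequences unpenalized, so very strong smoothing still
represents constant and (log-)linear parameter surfaces exactly while
suppressing spurious wiggle.  A `FitConfig(smoothing="fixed",
lambda_init=...)` override fixes the smoothing instead, and
`basis="constant"` fits one coefficient per curve without penalty (giving
exactly one effective df per parameter — this is also how the logit-normal
comparison baseline for AIC/BIC model selection is fitted).

Other conventions: 0·log 0 = 0 in all entropies; observations with t exactly
0 or 1 are nudged to (1e-6, 1 − 1e-6) before fitting (a non-inflated model
is used throughout); evaluating the null at sizes outside the training range
clamps s to [s_lo, s_hi] rather than extrapolating the splines; CDF values
are clipped away from {0, 1} by 1e-12 before normal-quantile inversion in
the residual diagnostics; analytic p-values are floored at 1e-300 before
logarithms in Fisher combinations.  Feature/GU overlap uses a ≥ 1-bp rule
(configurable to GU-midpoint containment); all coordinates are 0-based
half-open.  Promoters are 2·half_width windows (default 4 kb) centered at
the strand-aware TSS, floored at position 0; gene bodies are the gene
interval minus the promoter, with an empty sentinel when the promoter covers
the gene.  Default minimum feature sizes are K_min = 10 GUs for promoters
and gene bodies and 5 for custom features.

## What the synthetic cohort emulates — and what it does not

The generator mirrors the targeted study design: n_ref replicate reference
methylomes (default 4) and n_test test samples (default 3), each test
compared against a distinct reference so that the multi-comparison Fisher
combination operates on independent comparisons, exactly the assumption the
χ²_{2N_t} reference requires.  Every sample's per-GU level PMF comes from
the nearest-neighbor Ising forward model Pr[x] ∝ exp(Σ a_n x_n +
Σ b_n x_n x_{n+1}) (the simplest exponential-family form giving independent
control of mean methylation via the fields and of inter-CpG correlation via
the couplings); replicate variability is a per-GU Gaussian field shift
(sd 0.6), and planted features in test samples get a −3.0 field shift with
couplings scaled by 0.3 — hypomethylation with methylation-entropy gain, the
qualitative signature of aggressively demethylated tumors.  Base fields are
bimodal (70% N(0.8, 0.4), 30% N(−0.8, 0.4)) and couplings N(0.4, 0.2): the
mode separation is deliberately modest so that the replicate-discordance
scale is comparable across GUs.  If many GUs sat in saturated regimes, the
null T distribution would vary across features beyond what size s explains,
and the per-feature p-values of different comparisons would be correlated
through the shared base — breaking the independence that Fisher combination
assumes.  Features span 5–40 consecutive GUs (log-uniform) with 1-GU gaps;
5% of GUs per sample are masked as missing data.

The generator injects variability at the Ising-parameter level, not at the
read level: it does not emulate sequencing depth, bisulfite conversion
error, coverage-dependent estimation noise, or correlated (regional)
replicate effects.  Passing tests therefore demonstrate the statistical
machinery — calibration of the size-dependent null, FDR control, power
against planted effects — under an idealized but structurally faithful data
model; they do not certify performance on any particular real cohort, where
the practitioner should run the same goodness-of-fit diagnostics (quantile
residuals, centile coverage, AIC/BIC family comparison) before trusting the
ranking.

## Validation performed by the test suite

* Exact oracles: the level-PMF dynamic program against 2^L enumeration
  (L ≤ 12, 1e-12); mutual information against squared JSD (1e-10); the
  hand-written JSD against an independent library implementation; the
  empirical Fisher null against χ²₄ under independence (max |Δp| < 0.01 at
  N_r = 1e5).
* Metric axioms of JSD and the T triangle inequality on 1e4 random
  instances; exact attainment of T = 0 and T = 1.
* Parameter recovery of four generating surfaces (constant; linear μ;
  log-linear σ; mild ν, τ trends) at n = 20,000, with μ within ±0.05 on the
  constant surface and ln σ within 0.1 on the heteroscedastic one;
  held-out p-value uniformity (KS at α = 0.01); centile coverage within
  ±1.5% at n = 1e5; quantile-residual moments within (±0.05, ±0.05, ±0.1,
  ±0.2) of standard normal at n = 1e4.
* End-to-end: a 2,000-feature null cohort yields uniform per-comparison
  p-values and 3.5–6.5% of features at combined p < 0.05; ten planted
  cohorts yield pooled realized FDR ≤ 0.15 at q ≤ 0.1 and per-seed
  AUROC > 0.9.
* With strongly correlated promoter/body p-values the χ²₄ reference is
  demonstrably anticonservative while the empirical null restores
  uniformity — the rationale for the empirical T_pb CDF.

Problem sizes in the suite (cohorts of 2,000 features for calibration,
4,000-GU cohorts across ten seeds for FDR, n = 20,000 for regression
recovery) were chosen as the smallest at which the asserted tolerances are
statistically meaningful.

## Known limitations

* The empirical T_pb null pools across features; a per-size-stratified
  empirical null might be more faithful when promoter/body correlation
  varies with gene length.
* AIC-based smoothing selection can admit mild wiggle in the skewness curve
  on heteroscedastic surfaces (it optimizes fit, not curve recovery);
  p-value calibration is unaffected, which is the operative property.
* The tail parameter τ is weakly identified at moderate sample sizes; its
  curve is reported but should not be interpreted quantitatively.
* Ising parameter estimation from reads, DMR finding, and enrichment
  analyses are out of scope; the package starts from per-GU PMFs or JSD
  tracks.
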