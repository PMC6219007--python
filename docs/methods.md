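# Methods

## Model

Counts Y_gji (feature i, sample j, group g) are modeled through the ratio of
the sample's observed proportion to a dataset-average reference proportion
q₀ᵢ (the mean over samples of q̂ᵢ = Yᵢⱼ/τⱼ, renormalized to sum to one).
The ratio r = q̂/q₀ follows a hurdle log-normal:

- with probability π_gji the count is zero; logit(π) = β₁ᵢ + β₂ᵢ·log τ,
  one logistic fit per feature across all samples;
- otherwise log r = log ζ₀g + μ + a + ε, with a ~ N(0, η²₀g),
  ε ~ N(0, σ²₀ᵢ).

The estimand is the compositional correction factor Λ⁻¹ per sample: the
location of the net fold changes θ = Λ⁻¹ν, where ν is a feature's absolute
fold change relative to the control condition.  Under the working assumption
that log fold changes are centered at zero, a robust location estimate of θ
estimates Λ⁻¹.

Key identities the package relies on: a global fold change ν ≡ c is invisible
in proportions while scaling the net change Λ by c (this is the confounding
being corrected), and the conditional mean of a positive log-normal ratio
exceeds its location by e^(σ²/2) (the source of the de-biasing factor).

## Estimation

**Prior moments.**  ζ₀g is the arithmetic mean of group-pooled ratios
r_gi = (Y_g+i/Y_g++)/q₀ᵢ over usable features *including zeros*.  Including
zeros is essential: on sparse data the zeros carry most of the compositional
signal, and positives-only locations are biased toward unchanged or
up-shifted features.  η²₀g is the population variance (divide by count, not
count−1) of log pooled ratios over features observed in the group; a group
with fewer than two observed features falls back to the across-group value
with a warning.

**Feature noise σ²₀ᵢ.**  The per-feature variance of log sample-level ratios
over positive entries, moderated toward the grand mean with k₀ = 5
pseudo-observations — v = (k·s² + k₀·s̄²)/(k + k₀) — and floored at
εσ = 1e-4.  The moderation keeps rarely observed features (often k ≤ 2
positives) from reporting spuriously tiny or huge variances; the floor keeps
weights and the de-biasing factor finite in degenerate inputs.  This is a
deliberately simple moderated-variance estimator; it does not reproduce any
particular published variance-moderation pipeline, and the documented
formula is the contract.

**Location effects (pooling).**  By default (`pooling="pooled"`) μ̂ and â
are estimated from the *group-pooled* ratios: μ̂_g is the precision-weighted
mean of centered log pooled ratios (weights ∝ 1/(σ²ᵢ + η²g)), and
â_gi = κᵢ·(log r_gi − log ζ₀g − μ̂_g).  ζ₀g·e^(μ̂_g) is then a
precision-weighted *geometric* location of the pooled ratios, which is far
more robust to the multiplicative contamination injected by genuinely
changed features than the arithmetic ζ alone; sample-level resolution enters
through the hurdle probabilities, the W-weights and the depths.  The
alternative `pooling="sample"` estimates μ̂ and â per sample from its own
positive ratios.  It gives fully sample-specific factors but is vulnerable
to a selection bias on sparse data: the features that remain positive in a
heavily compressed sample over-represent up-shifted features, inflating μ̂
for exactly the samples that need correction most.  The pooled default was
adopted after quantifying this bias on simulated data (roughly a three-fold
larger group-scale log error under sample-level pooling at 10K reads);
users with dense data and strong per-sample scale variation may prefer
`pooling="sample"`.

**Shrinkage orientation.**  `shrinkage="blup"` (default) uses
κ = η²/(σ² + η²), the best linear unbiased predictor of a N(0, η²) effect
observed with noise σ²: residuals vanish as the prior variance goes to zero.
`shrinkage="printed"` uses the transposed κ = σ²/(σ² + η²), which shrinks
feature deviations *more* when the fold-change spread η² is large — a
robust-location convention rather than a prediction convention.  Both are
defensible for this estimator and both are exposed; the degenerate cases
(η² = 0, σ² at floor) behave sensibly under either.

**Hurdle fit.**  One logistic regression per feature of the zero indicator
on intercept + log depth, all features solved simultaneously by vectorized
Newton iterations (shared design matrix).  A ridge penalty λ = 1e-3 on the
slope keeps the fit defined under separation and collinearity: with constant
depths the slope collapses to zero and the intercept-only solution — the
empirical zero fraction — is recovered.  Working weights are bounded away
from zero (linear-predictor clip at ±15 inside the solver), coefficients are
capped at ±60, and fitted probabilities are clipped to [επ, 1−επ] with
επ = 1e-6.  Never-zero and always-zero features skip the solver and return
the clipped constants.

**Averaging (W0–W3).**  With θ̃ = θ̂·e^(−σ²ᵢ/2) (flag `debias`, default on),
the per-sample factor is a weighted mean over usable features: W0 unweighted;
W1 with w ∝ 1/(1−π̂); W2 (default) with w ∝ 1/[(1−π̂)(π̂ + e^(σ²ᵢ+η²g) − 1)],
the inverse marginal variance under the hurdle log-normal; W3 averages
θ̃/(1−π̂) with w ∝ 1/σ²ᵢ.  Weights are normalized to sum to one per sample,
making the estimators scale-determinate.

**Identifiability and centering.**  Because the reference is the dataset
average rather than the control group, Λ̂⁻¹ is identified only up to a
constant; ccf and nf = ccf·τ are therefore rescaled to unit geometric mean by
default (`centering="none"` disables this).  Comparisons against ground truth
anchor on the control group instead (below).

**Degenerate inputs.**  Features absent from every sample have q₀ = 0 and
are masked from all ratio computations (they receive no θ̂ and are reported
via the mask).  All-zero samples are rejected at load.  A sample (or group,
under pooled mode) with no positive usable features raises an error naming
it.

## Baselines

Total-sum (Λ⁻¹ ≡ 1); TMM with the standard published defaults (reference
sample chosen as the one whose upper-quartile proportion is closest to the
mean of upper quartiles, 30% two-sided trim on M, 5% on A, inverse
delta-method binomial variance weights, log base 2; rank-based trimming with
stable tie order); DESeq-style median-of-ratios (geometric-mean
pseudo-reference over features positive everywhere; even-length medians are
the mean of the central pair); median and upper-quartile proportions over all
features, zeros included, with linear quantile interpolation; CLR factors as
the geometric mean of pseudocounted proportions (pseudocount 1, natural
scale); and CSS with a fixed configurable quantile (default 0.5) of the
*positive* counts — the original adaptive quantile-selection rule is out of
scope and documented as such.  Failures (no shared features with the TMM
reference, no ubiquitous feature for median-of-ratios, zero quantiles) are
surfaced as per-sample or dataset-level markers with machine-readable
reasons, never silent NaNs.

## Simulator

The generator injects compositional bias the way it arises physically:
fold changes are applied to a control proportion vector and *renormalized*
before multinomial read sampling, so the net change Λ_gj = Σᵢ ν_gji·q₁ᵢ is
recorded as ground truth but invisible to library-size normalization.
Independent Poisson/NB simulation cannot create this confound, which is why
the generator exists as first-class, tested code.

Defaults (the study conditions used throughout the tests and the acceptance
script): Gaussian prior log fold changes with mean 0 and standard deviation
3, applied to a fraction f of features chosen without replacement with
probability proportional to their control proportion (perturbing rare
features induces negligible compositional bias); per-sample log-normal
jitter of the fold changes with variance σ̃²ν = 0.01, applied to all
features of non-control groups; log-normal depths with log-mean log(depth)
— so `depth_mean` is the median depth — and log-sd 0.25; and, when no
control proportions are supplied, a synthetic heavy-tailed profile
(exponentiated Gaussian with log-sd 3, renormalized).  The log-sd 3 default
was chosen so that the default configuration (p = 5000 features at 10K
reads) reproduces the per-sample zero fractions of real 16S surveys
(median ≈ 0.9, within the 0.85–0.98 range seen in practice); a log-sd of 0
degenerates to the uniform profile.  The control group carries ν ≡ 1 and
Λ ≡ 1 exactly and anchors all ground-truth comparisons.  A user-supplied
control-proportion vector (e.g. derived from a real survey) replaces the
synthetic profile without any download dependency.  Depths are rounded to
the nearest integer and floored at 1; counts sum to the drawn depth exactly.

The **expansion toy** is a synthetic ten-feature construction for the
zero-truncation phenomenon: one dominant taxon (35% of control reads)
expands 50-fold (log2 fold change 5.64) while the nine remaining features
split the rest equally.  The depth default (median 80 reads) is set so the
construction's premise actually holds: the rare features are essentially
always observed in controls but mostly drop out of case samples, and the
few that survive do so with truncation-inflated counts.  Positives-only
normalizers then underestimate the compositional change; zero-aware
estimation does not.

What the simulator does **not** emulate: taxon-taxon correlations,
overdispersion beyond the fold-change jitter (no negative-binomial layer),
batch effects, contaminant sequences, or chimeras.  Passing tests on this
generator therefore demonstrate correct behavior under multinomial sampling
with compositional renormalization, not robustness to every artifact of
real surveys.

## Evaluation harness

**Testing engine.**  A per-feature negative-binomial log-linear model with
the normalization factors as offsets and a likelihood-ratio test (χ², 1 df),
fitted by vectorized Newton–Raphson across features (expected-information
updates, 1e-8 ridge on the information matrix, step clip ±3).  Dispersions
are per-feature method-of-moments estimates shrunk toward a rolling-median
trend over features ordered by mean normalized count (window ≈ p/20, raw
weight 0.3) and floored at 1e-8.  A Welch option tests log2((Y+0.5)/nf).
No numeric parity with any external testing package is claimed; all
comparisons between normalizers hold the engine fixed, which is what the
comparison requires.  Multiple testing uses Benjamini–Hochberg at FDR 0.1
(statsmodels' implementation behind the `bh_adjust` surface, cross-checked
in the tests against a direct transcription of the step-up rule).

**Detectable truth.**  Features called significant when the engine is given
the *true* factors nf = τ·Λ⁻¹ form the reference set, with signs.
Sensitivity is the fraction of that set recovered with the correct sign;
false discovery counts wrong-signed true features and non-true features
among the significant calls.  Empty call sets yield false discovery 0; an
empty truth set leaves sensitivity undefined (NaN).

**Reconstruction error.**  Λ̂ = 1/ccf is rescaled so the control group's
mean matches the control truth, and the signed and absolute means of
log(Λ̂/Λ) over non-control samples are reported, along with the fraction of
samples a method failed on.  Anchoring on the control group is this
package's convention for resolving the scale indeterminacy.

**False-positive experiments.**  The resampling experiment repeatedly splits
one homogeneous group (≥ 15 samples) in half, tests with each method's
factors (computed once on all data), and reports per-iteration
log2(F_method/F_wrench) call-count ratios with a +0.5 continuity offset
applied to both counts when either is zero.  The offset-covariate experiment
fits, per feature, one method's log factors as offset with the competitor's
as a standardized covariate and counts significant covariate terms in both
directions; factors collinear after logging (correlation 1) are reported as
zero counts by convention, since the covariate then carries no information
beyond the offset.

## Problem sizes

The test suite and the acceptance script run on deliberately scaled-down
designs chosen to exercise every regime the package targets: p = 1000–5000
features, 10–20 samples per group, depths of 4K–10K reads, 10–20 replicates
per stochastic assertion.  These sizes make every stochastic claim cheap to
re-verify while preserving the sparsity (0.8–0.95 zero fractions) that
defines the problem.

## Known limitations

- Under the default benchmark conditions — mass-weighted feature selection
  with sd-3 log fold changes on a heavy-tailed profile — most of the read
  mass is genuinely perturbed and the realized net changes Λ are large
  (often 10–90×).  A feature whose fold change happens to be close to Λ is
  then *information-theoretically indistinguishable* from an unchanged
  feature (its proportion ratios do not move), so every ratio-based
  estimator carries an irreducible bias that grows with log Λ.  Wrench
  reduces this error several-fold relative to library-size and
  positives-only normalizers but does not eliminate it; the acceptance
  script reports the measured recovery errors side by side.
- The hurdle model attributes zero generation to feature identity and depth
  only; group covariates are not included in the logistic fit.
- Factors are estimated jointly on the full matrix; `transform` applies only
  to the fitted data, and there is no out-of-sample projection.
- No batch correction, no continuous covariates, no gene-length adjustment;
  two-group designs are the tested default for the simulator and the
  testing engine (the normalizer itself accepts any number of groups).
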