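# Methods

## Generative model of a trial

A trial presents a category C ∈ {1, 2} (equiprobable by design), a
stimulus orientation s drawn from the category's Gaussian distribution,
and one of six physical reliability levels c (defaults: the Gabor
contrasts 0.004, 0.008, 0.017, 0.033, 0.067, 0.135; ellipse
eccentricities 0.15–0.8 are available as an alternative preset).  The
observer receives a noisy measurement

    x ~ N(s, σ(c, s)²)

with measurement noise s.d.

    σ(c, s) = sqrt(σ_L² + (σ_L² − σ_H²)(c^−β − c_L^−β)/(c_L^−β − c_H^−β))
              + ψ·|sin(π s / 90°)| .

This is the power-law variance relationship σ²(c) = γ + α c^−β
reparameterized so that σ_L and σ_H are the measurement s.d.s at the
lowest (c_L) and highest (c_H) calibrated reliabilities and β controls
curvature between them; the rectified 2-cycle sinusoid captures higher
noise at oblique orientations.  A nonparametric variant replaces the
power law with one free s.d. per reliability level.  Measurements are
Gaussian rather than Von Mises: the orientation range in these tasks is
narrow enough that the circular correction is negligible.

Orientation convention: degrees, 0° horizontal, positive rightward.
Category 1 is the leftward (Task A) or narrow (Task B) category, so the
log posterior ratio d = log p(C=1|x) − log p(C=2|x) is positive for
negative x in Task A.  (The equations fix this convention; prose
descriptions of such tasks sometimes state the opposite sign.)

## Decision variables and boundaries

Marginalizing the unknown stimulus gives p(x|C) = N(x; μ_C, σ² + σ_C²),
hence

    d_A = 2 x μ₁ / (σ² + σ₁²) + log p(C=1)/p(C=2)
    d_B = ½ log[(σ² + σ₂²)/(σ² + σ₁²)]
          − x² (σ₂² − σ₁²) / (2 (σ² + σ₁²)(σ² + σ₂²)) + log p(C=1)/p(C=2).

The Bayesian confidence hypothesis states that the combined
category-and-confidence report depends on x only through d: the
response is determined by comparing d to criteria k₀ = −∞ < k₁ … k₇ <
k₈ = ∞, with k₄ separating the categories.  Three strengths are
implemented: **ultrastrong** (one symmetric criterion set shared by both
tasks; 4 free boundary parameters in a joint fit), **strong** (one
symmetric set per task; 8), and **weak** (symmetric in Task A, free in
Task B; 11).  Criteria on d are converted to measurement-space
boundaries in closed form: Task A boundaries are affine in σ², Task B
boundaries act on |x| with unreachable criteria collapsing to 0 (the
narrow-category region vanishes).  d-noise variants add zero-mean
Gaussian noise with s.d. σ_d to d; response probabilities marginalize
over 101 evenly spaced draws of the noise spanning ±5σ_d (capturing
essentially all mass; the span is configurable) with Gaussian weights.
Because the criterion inversion is analytic, the shifted criteria
k − η_d are inverted exactly rather than through an interpolation table.

Non-Bayesian families replace d: **Fixed** compares x to constant
criteria; **Lin** and **Quad** to criteria k_r + m_r σ and k_r + m_r σ²
(supermodels of Fixed, and — in Task A — Quad nests the no-d-noise
Bayesian observer exactly); **Orientation Estimation** compares the MAP
orientation estimate ŝ(x, σ) = argmax_s N(s; x, σ²)(p(s|C=1)+p(s|C=2))
to criteria; ŝ is tabulated on a 500-point x grid × 50-point log-σ grid
(monotone-cubic in log σ), the table brackets each criterion crossing,
and bisection on the exactly evaluated estimate refines the boundary —
necessary because ŝ(x) jumps discontinuously where the posterior is
bimodal, so pure interpolation converges only linearly.  Halving the
table resolution changes dataset log likelihoods by far less than 0.1; **Linear Neural**
reads out z = w·r from a homogeneous Poisson population with Gaussian
tuning curves of width σ_TC, gain g = 1/σ² and weights w = a·s̃, giving
E[z] = a g s √(2πσ_TC²) and Var[z] = a² g √(2πσ_TC²)(σ_TC² + s²) (the a²
follows from w² in the variance sum and is confirmed by direct
simulation of the population); **Precision-hybrid** applies confidence
criteria to v = ω/σ² + logistic(|d|) and takes the category from d
against its own criterion, like the ultrastrong set it has 4 boundary
parameters.

Fitted criteria are not constrained to be ordered; crossing boundaries
(and crossing hybrid confidence bands) are resolved by sorting per σ, so
response regions always partition the measurement axis and no response
receives negative mass.

## Response probabilities and lapses

For boundary models the core probability of response r is the mass of
N(s, σ²) between consecutive boundaries (Task A), or over the mirrored
pair of |x| intervals with b₀ = 0 (Task B).  Interval masses are
computed from the normal CDF evaluated on the nearer tail of each edge,
so far-tail intervals never suffer catastrophic cancellation.  The core
vector is mixed with three mutually exclusive lapse processes (their
probabilities add; the combination rule is a package decision):

- full lapse (λ_full): category uniform; confidence from the
  distribution with endpoint weights λ₁ (level 1) and λ₄ (level 4),
  linear interpolation in between, renormalized to sum 1;
- confidence lapse (λ_conf): category marginal kept, confidence uniform;
- repeat lapse (λ_repeat): the previous response is repeated.  On the
  first trial the repeat mass is redistributed proportionally over the
  other components.

Choice-only model variants use a 2-vector (category lapse λ and repeat
lapse only).  The dataset log likelihood is the sum of log response
probabilities over testing trials; training trials are generated for
structural fidelity but never analyzed.

## Parameterization and priors

All parameters are sampled on a scale on which the prior is a uniform
box: s.d.-like parameters (σ_L, σ_H, per-level σs, σ_d, σ_TC, fitted
category s.d.s, the readout scale a) are log-transformed (log-uniform
priors), everything else is linear.  Default ranges (overridable):
d-criteria ∈ [−20, 20]; measurement-space criteria and slopes ∈
[−90, 90]°; z-criteria ∈ [−10⁴, 10⁴]; v-criteria ∈ [0, 10³];
s.d.-like parameters ∈ [0.1°, 50°] (σ_d ∈ [0.01, 10]); β ∈ [0.1, 10];
ψ ∈ [0, 10]°; ω ∈ [0, 100]; lapse rates ∈ [0, 0.3] with full-lapse
endpoints λ₁, λ₄ ∈ [0, 1]; fitted log prior ratio ∈ [−3, 3].  The
reference analysis chose "reasonable, sufficiently large" ranges without
printing them; these defaults play that role and the parameter-recovery
tests are run under them.

## Inference

The log posterior is the dataset log likelihood plus the (constant
inside the box) log prior.  Sampling uses univariate stepping-out /
shrinkage slice sampling cycled over coordinates; chains start from
prior draws (rejecting non-finite posteriors, up to 100 tries) or from
user-supplied points, with initial widths of 1/10 of each prior range.
After the burn-in third the widths are retuned to 2.5× the local
posterior scale — slice-width choice affects only efficiency, never the
invariant distribution.  Chain processing follows the reference
procedure: discard the first third, keep a target number of evenly
spaced draws per chain, drop draws whose log posterior is more than 40
below the retained maximum.  Convergence is checked by split R-hat and
bulk effective sample size (computed where the visual check sat in the
original workflow); R-hat > 1.05 raises a warning flag, not an error.
The desk-scale default (4 chains × 10⁴ samples) is far below the
full-scale runs (40,000–600,000 samples, 6,667 kept); a full-scale
configuration is a `ChainConfig` away but no test requires it.

Maximum-likelihood fitting (used by the recovery harness) is bounded
L-BFGS-B inside the prior box, best of several restarts; parameters can
be frozen at known values (`frozen=`), which the calibration study uses
to hold nuisance noise-shape parameters at their generating values.

## Model comparison

AIC = −2ll + 2n, BIC = −2ll + n log t, AICc = AIC + 2n(n+1)/(t−n−1)
(flagged missing when t ≤ n+1), with the highest-likelihood posterior
draw standing in for the MLE.  WAIC = lppd − Σᵢ Var_u log p(rᵢ|θᵤ).
PSIS-LOO smooths the largest 20% of importance ratios per trial
(M = min(0.2S, 3√S) tail draws) with a generalized-Pareto fit by
probability-weighted moments, replaces them by expected order
statistics, truncates weights at S^¾ times the mean weight, and reports
the tail index k̂ per trial (warning above 0.7).  Metrics are compared on
a common scale (−IC/2) by Spearman rank correlation.  Scores aggregate
across subjects by the summed-difference bootstrap: per-dataset
differences from a reference model, datasets resampled with replacement
10,000 times, median and central 95% interval of the resampled sums.

Model recovery generates datasets from each candidate model, fits every
candidate by MLE, scores with AIC, and tabulates mean ΔAIC per
(generator, fitter) plus the correct-selection rate.  Generating
parameters come from a subject-plausible sampler (noise of a few degrees
falling with reliability, ordered criteria spanning the stimulus range,
lapse rates of a few percent) rather than the full prior box — the
reference analysis used subject-fitted parameter draws, and prior-box
draws routinely produce degenerate response distributions that make
recovery uninformative.  Within the measurement-space families the fits
run in nested order and Lin/Quad are warm-started from the Fixed
solution with zero slopes, equalizing optimization quality across
fitters.  Group-level random-effects model selection (protected
exceedance probability and expected posterior probability) is exposed
nowhere: the reference analysis delegated it to external software and it
is out of scope here.

## Synthetic data: what it does and does not emulate

`generate_dataset` reproduces the session/block arithmetic of the
experiments (experiment 1: 5 sessions × both tasks × [3×96 category
training, 1×24 confidence training, 3×144 testing] = 2880/240/4320
trials; experiments 2–3 totalled 3240 testing trials with an unprinted
per-block split, so their structures are configurable presets).
Responses come from any registered observer model, including its lapses,
with category training at the highest reliability only.  Random draws
are consumed column-wise per block (categories, stimuli, reliabilities,
measurements, decision noise, lapse draws) from a single seeded
generator, so identical seeds give bitwise-identical CSV files.  The
simulator shares no response-probability code with the likelihood
module beyond the boundary computation, which is why binned simulated
frequencies vs analytic probabilities is the central joint correctness
test.

Not emulated: stimulus rendering, reaction times, feedback-driven
learning (performance is stationary by assumption), or any trial-history
effect beyond the repeat lapse.  Passing tests therefore show that the
pipeline is self-consistent and calibrated under its own generative
assumptions — not that real observers satisfy them.

## Problem sizes used by the tests

The end-to-end checks run at desk scale, chosen to exercise each claim
at the sample sizes where it is informative: simulator-vs-likelihood
agreement uses 10⁵ draws per stimulus cell (4 binomial s.e. criterion,
≥ 95% of cells); parameter-recovery calibration uses 20 replicate
4320-trial datasets of a choice-mode Quad observer (its six parameters —
noise endpoints, boundary offset and slope, two lapse rates — are
mutually identified, avoiding the label-switching ambiguity of unordered
confidence criteria) with 2 chains warm-started from a quick MLE;
cross-metric agreement uses a 3-model choice group on 4320-trial
datasets; recovery uses 4 families × 4 Task-A datasets of 4320 trials.
The boundary-identity and conjugate-oracle checks are exact or
closed-form and run at full precision.

## Known limitations

- The orientation-estimation inversion assumes a monotone ŝ(x) profile;
  non-monotone table rows (possible at extreme σ) fall back to the
  nearest crossing with a warning.
- Posteriors over unordered criterion sets are permutation-multimodal;
  MCMC summaries of individual criteria are only meaningful once chains
  have settled into one labeling (the R-hat flag marks failures).
- PSIS-LOO k̂ > 0.7 indicates an unreliable importance-sampling tail for
  that trial; the package warns but does not refit.
- The d-noise grid is a quadrature approximation; its 101-point
  resolution matches the reference procedure and leaves discretization
  error far below simulation error at the tested sample sizes.
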