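# Methods

## The observer model

The package models spatial localization of brief auditory and visual
events in azimuth (degrees; negative = left of fixation).  On each trial
a stimulus appears at one of five speaker positions (−13°, −6.5°, 0°,
+6.5°, +13°) in one modality or both.  The observer never sees the true
location s; it receives internal measurements

- x_A ~ Normal(s_A·(1 + Δx_A), σ_A)
- x_V ~ Normal(s_V·(1 + Δx_V), σ_V + Δσ_V·|s_V|/6.5)

The gain form of the bias (mean = s·(1+Δx)) makes the measurement shift
grow linearly with eccentricity and vanish at fixation, matching the
behavioral observation that localization errors grow with eccentricity;
negative Δx compresses toward the center, positive Δx expands outward.
One 6.5° speaker step is the unit of the visual noise growth Δσ_V.  Only
the visual likelihood SD scales with eccentricity; the auditory SD is
constant.

Inference proceeds in the standard causal-inference form.  The observer
evaluates the evidence that both measurements share one source,

p(x_A, x_V | C=1) = ∫ p(x_A|s) p(x_V|s) p(s) ds,

against the evidence for independent sources (the product of the two
single-cue integrals), combines them with the binding prior P_c, and
reports posterior-mean estimates — the fused mean under C=1, the
modality-specific conditional means under C=2.  The decision between
them is probability matching: one uniform draw ξ per trial, shared by
the two modalities; the fused estimate is reported when p(C=1|x) > ξ.
Unisensory trials bypass causal inference.

Crucially, the observer's inference assumes *unbiased, baseline-noise*
likelihoods — it does not know its own Δx and Δσ_V, and it cannot
condition the noise level on the unknown stimulus.  The response biases
arise precisely from this mismatch between the generative measurements
and the observer's internal model.

### Priors

Three prior mechanisms exist and compose by (normalized) multiplication:

- a metamodal central Gaussian N(x_P, σ_P), shared by both modalities;
- a visual central Gaussian N(x_VP, σ_VP);
- an auditory peripheral prior: an equal-weight mirrored pair of
  Gaussians at ±x_AP with common σ_AP.

A modality's segregated (C=2) posterior uses its own prior times the
metamodal prior where present; the common-cause posterior uses the
normalized product of all active priors.  Observers with no prior
mechanism use a proper uniform on [−45°, +45°] (the stimulus range is
±13°, so results are insensitive to the exact halfwidth; the uniform
keeps all evidences normalizable).  All posterior means and evidences
have closed forms: Gaussian mixtures compose conjugately, and the flat
prior yields truncated-normal expressions.  These closed forms are
cross-checked against trapezoid quadrature oracles (0.001° grid) to
relative 1e−6 in the test suite.

### Model variants

Six variants are compared; all share {P_c, σ_V, σ_A}.  `M4_original` is
the classical baseline: unbiased likelihoods plus a zero-mean metamodal
Gaussian prior (only σ_P free).  `M5_likelihood`/`M6_likelihood_var` put
the bias in the likelihood means (M6 adds Δσ_V) with a flat prior.
`M8_hybrid` adds a free-mean metamodal prior to M6.  `M7_priors` puts
the bias entirely in the priors (visual central + auditory mirrored
pair), and `M9_priors_meta` adds the metamodal prior to M7.

Box bounds: P_c ∈ [0,1]; likelihood SDs ∈ [0.1, 30]°; Δx ∈ [−0.5, 0.5];
Δσ_V ∈ [0, 3]°/step; prior means ∈ [−30, 30]°; x_AP ∈ [0, 30]°.  Prior
SDs are bounded [1, 200]°: the upper bound is deliberately far above the
stimulus range so that a Gaussian prior can become effectively flat,
which is what makes the flat-prior variants (M5, M6) genuine nested
special cases of the prior-bearing ones (a prior SD capped at 30° would
still shrink an 8°-noise auditory cue by ~7% and break the nesting).

## Response likelihood and fitting

The response likelihood has no closed form.  Following the generative
logic, each candidate parameter set is scored by simulating the observer
for every stimulus condition, binning simulated responses on a 1° grid
over [−45°, +45°] (a 90×90 joint auditory×visual histogram for bisensory
conditions), smoothing, normalizing, and summing the log probability of
each observed trial's bin.  Responses are quantized to the 0.1°
device resolution before binning; out-of-range responses fall into edge
bins.

Numerical choices that matter:

- **Smoothing.**  The predicted distribution is mixed with a uniform
  component, parameterized as 0.5 pseudo-counts per bin at the reference
  10,000 simulations and scaled proportionally at other simulation
  counts, so the smoothed prediction is the same mixture at any
  simulation size and no observable response ever has zero probability.
- **Common random numbers.**  The simulator consumes scrambled-Sobol
  quasi-random draws cached per seed, so the objective is a
  deterministic function of the parameters, identical across optimizer
  evaluations and across models.  Quasi-random stratification greatly
  reduces the histogram error at a given simulation count.
- **Rao-Blackwellized decisions.**  Inside the fitting objective the
  probability-matching draw is marginalized analytically: each simulated
  sample contributes weight p(C=1|x) to its fused joint bin and
  1 − p(C=1|x) to its segregated joint bin.  The expectation is
  identical to sampling ξ (which `predict_response_distribution` still
  does); the variance is far lower, which keeps the objective smooth
  enough for derivative-free optimization.  Simulation counts are
  rounded up to powers of two, as Sobol balance requires.
- **Optimization.**  Powell's method in an unconstrained
  reparameterization (logit for P_c and other box-bounded parameters,
  log-scaled logit for SDs), from a moment-based start (unisensory
  regression slopes and residual SDs, the near-coincidence rate of
  congruent bisensory responses) plus Latin-hypercube multistarts.
  Powell was chosen over simplex search after the latter repeatedly
  stalled in the curved P_c/σ_A trade-off valley.  When several models
  are fitted to the same observer (`fit_models`), richer models are
  additionally warm-started from the best nested fit; swapping the flat
  prior for a wide Gaussian shifts the common-vs-independent evidence
  ratio by the constant log(2h / (σ_P√2π)), which the embedding absorbs
  into P_c on the logit scale.
- **Final evaluation.**  Whatever simulation count the search used, the
  reported log likelihood (and BIC, and pseudo-R²) is re-evaluated at
  the final count with the same seed, so model comparisons share their
  Monte-Carlo noise.

A fused numba kernel implements the per-sample generative pass; the
vectorized numpy implementation is retained as the reference and the two
are asserted to agree (≤ 1e−4 nats) in the tests.  The kernel's flat
prior path uses an erf polynomial approximation accurate to 1.5e−7.

Goodness of fit is summarized by a pooled pseudo-R²: 1 − SSE/SST between
predicted bin probabilities and empirical bin frequencies, concatenated
over all conditions and floored at zero.  This is a declared convention,
not a claim of identity with any particular published R² formula.

## Synthetic cohorts

The generator emulates the printed design: 5 auditory-only + 5
visual-only + 25 bisensory conditions, 15 trials each, pseudorandom
order, responses rounded to 0.1° and clipped at the screen edge
(±64.9°; clip events are logged).  Default generating parameters for
demonstration cohorts are P_c = 0.55, σ_V = 2.2°, σ_A = 8.5°,
Δx_V = −0.12, Δx_A = +0.25, Δσ_V = 0.6°/step, σ_P = 25°, x_P = 0 —
illustrative values chosen to reproduce the qualitative behavioral
signatures (central visual bias ≈ 1.5° at ±13°, peripheral auditory bias
of similar size, eccentricity-growing visual SD), not estimates from any
dataset.  Note that the metamodal prior shrinks auditory responses by
σ_P²/(σ_P²+σ_A²) ≈ 0.90, so a net peripheral auditory bias requires
Δx_A > σ_A²/σ_P² ≈ 0.12; Δx_A = 0.25 leaves a ≈ +1.5° outward bias at
±13°.  Between-observer variability is modeled as independent truncated
normal draws per parameter (SDs: 0.10 on P_c, ≈ 18% on the σ's, 0.04 on
the Δx gains, 0.2 on Δσ_V, 3° on σ_P, 1° on prior means); these SDs are
stipulated, since no per-observer estimates are published.

What the generator does *not* emulate: eye movements, practice trials,
response-time structure, motor noise beyond the 0.1° quantization,
lapses, or the excluded "sloppy" responders.  Passing recovery and
model-selection tests therefore show that the pipeline is correct and
well-powered *under the model's own assumptions*, not that real data
would be fitted equally well.

## Descriptive analyses

- **Exclusion:** per unisensory condition, the cohort's per-subject mean
  responses give a robust SD (IQR/1.349); a subject deviating from the
  cohort median by more than 3× that value in any of the 10 unisensory
  conditions is excluded.  ("3× the inter-quartile standard deviation"
  is ambiguous in the source; the IQR-based robust SD is our reading.)
  Zero-IQR conditions are skipped with a warning.
- **Bias/precision tables:** mean(response − true location) and response
  SD per subject × modality × condition; positive = rightward.
- **Causal classification of congruent bisensory trials:** |r_V − r_A| ≤
  2° → common cause; > 5° → independent; the ambiguous band in between
  is excluded.  Boundaries follow the quoted phrasing (≤ inclusive,
  > exclusive).
- **Group tests:** Bonferroni-corrected one-sample t-tests of the eight
  peripheral bias cells (central cells reported uncorrected); one-way
  repeated-measures ANOVA (no sphericity correction) on response SDs
  across the five locations per modality, via pingouin, with the
  degenerate no-location-effect case returned as F = 0; paired t-tests
  between adjacent locations.

## Known limitations

- The binned Monte-Carlo likelihood is a biased (smoothed) estimate of
  the true response likelihood; all models are scored with the same
  smoothing and draws, so comparisons are on equal footing.
- With a weak generating metamodal prior (σ_P = 25°), the baseline-vs-
  hybrid distinction is only weakly identified from 525 trials: a
  zero-mean Gaussian prior acts on unisensory responses exactly like a
  linear gain plus SD change, which the likelihood-bias parameters can
  absorb; identification rests on the bisensory coupling alone.  The
  model-selection studies report what this actually yields rather than
  assuming the richest model must win.
- Problem sizes in tests and the acceptance script (cohort sizes 12–24,
  search simulation counts 1024–2048, final counts 4096–16384) are the
  package's default study sizes for desk-scale reproduction; all are
  options that can be raised.
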