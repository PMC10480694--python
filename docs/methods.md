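# Methods

This note records the models, conventions and numerical choices behind
`rollcall`, and what the synthetic-data tests do and do not demonstrate.

## Dive detection

Plunge dives are detected on the surge (x) axis alone: an event is a
maximal run of samples where the trailing 2-s running mean of x is
below 0 g *and* the trailing 2-s running sample SD (n−1 denominator)
exceeds 1.4 g. The thresholds are the standard ones for gannet-type
plunge signatures; both are configurable (`DetectionParams`).

Choices the threshold rule itself does not fix:

* **Window alignment.** Windows are trailing (causal), so a dive start
  is never pulled earlier by future samples. The first incomplete
  window of a trace is warm-up, emitted as NaN and excluded. The cost
  of causality is a detection latency of roughly 0.3–0.7 s at the
  default signal regimes, which the pre-dive window inherits.
* **"SD in the mean x-axis"** is read as the running SD of raw x over
  the same 2-s window, not the SD of the already-smoothed running-mean
  series: a 1.4 g threshold is implausible for a smoothed series, and
  the raw-window reading matches common biologging practice.
* **Segmentation.** Qualifying runs closer than `min_gap_s` (default
  10 s) are merged — re-entries seconds apart are one attempt — and
  merged runs shorter than `min_duration_s` (default 0.5 s) are
  discarded as noise. Both are explicit artifact parameters with no
  field-standard value; they are logged with every output.
* Event start = first sample of the qualifying run; the pre-dive
  window is anchored there.

## Roll

For quasi-static postures the accelerometer measures gravity, so roll
(rotation about the surge axis; negative = bird's left) is estimated
from the lateral/vertical balance of the measured vector. The default
convention is `atan2(y, sqrt(x² + z²))·180/π`, range (−90°, +90°] —
the standard accelerometer roll estimate, robust to pitch. An alternate
`full_range` convention `atan2(y, z)` spans (−180°, +180°] and is the
right choice if inverted postures must be distinguished; with it, a
circular mean is available for window averaging. The convention in
force is recorded in outputs; it is never inferred.

Per-second roll averages the raw (x, y, z) vector within each whole
second *before* taking the angle, suppressing zero-mean flapping
acceleration. The per-dive score is the arithmetic mean of per-sample
roll over the half-open window [t_start − 5 s, t_start), so the dive's
own first sample never contributes; 5 s is the field-observed duration
of the pre-dive roll manoeuvre. Averaging per-sample (rather than
per-second) values is the default; angles in this application sit far
from the ±180° wrap, so arithmetic averaging is safe under the default
convention.

A dive whose window mean is exactly zero is a tie: deterministically
assigned "right", flagged, and excluded from the index by default
(a measure-zero event on real data that must not be left to float
noise). A dive with an empty pre-dive window (recording gap) raises and
is excluded and counted by the pipeline.

## Lateralization

`LI = (Rd − Ld)/(Rd + Ld)` is computed in exact rational arithmetic
before float conversion. Classification is strict: `LI > 0.25` right,
`LI < −0.25` left, `|LI| ≤ 0.25` neither — lateralized means strictly
beyond the boundary. Birds with fewer than 5 classified dives are
flagged low-confidence but still classified (the threshold is
configurable; no minimum is standard).

Population percentages are reported as integers (round-half-up), so
they can disagree with exact shares by at most 1 point. The group
comparison is the two-sided Wilcoxon rank-sum test: exact null
distribution when the pooled sample has ≤ 20 values without ties,
normal approximation with tie correction otherwise; two identical
constant groups return p = 1 by convention. Post-hoc power for the
left/right split uses Cohen's h = 2·asin(√p₁) − 2·asin(√p₂) and the
normal-approximation power of the two-sided one-sample proportion test,
Φ(|h|√n − z_{α/2}) + Φ(−|h|√n − z_{α/2}), which equals α at h = 0 and
is monotone in |h| and n.

## Repeatability

Repeatability of a grouping factor is the variance ratio
R = σ²_group / (σ²_id + σ²_date + σ²_resid) from a crossed
random-intercept mixed model (bird and calendar day crossed, not
nested: days are shared weather/sea-state conditions, not bird-specific
sessions; a nested reading is possible but not the default).

* **Roll direction** (binary, 1 = left): logit GLMM fitted by the
  Laplace approximation — for candidate variances the joint penalised
  log-likelihood is maximised over fixed effects and all random
  intercepts by damped Newton iterations, and the marginal
  log-likelihood is the penalised optimum minus
  ½·log det(I + D^{1/2} Z'WZ D^{1/2}). The outer optimisation runs
  Nelder–Mead on log-variances. Reported residual variance is the
  logistic link variance π²/3, making R latent-scale; an
  observed-scale R (Gauss–Hermite integration of the logistic mean) is
  a secondary output. Birds that roll exclusively to one side are
  *not* dropped: the Gaussian penalty keeps their intercepts finite,
  which is precisely why the integrated likelihood is required here.
  Against lme4's Laplace implementation the fitter agrees to ~0.005
  log-units; against exact quadrature the Laplace approximation itself
  carries an O(0.1) log-unit error at ~20 observations per bird, a
  known property of Laplace for Bernoulli data that shrinks with group
  size and barely moves the variance estimates.
* **Roll angle**: the response is the roll *intensity* — the absolute
  pre-dive mean roll, degrees from horizontal — not the signed angle.
  Side and intensity are separate traits; on the signed angle a
  handedness-class covariate would mechanically absorb almost all
  bird-level variance, whereas intensity isolates "how far the bird
  rolls" from "which way". Fitted by REML (ML optional), profiling the
  residual variance and fixed effects out of the criterion and
  optimising the two variance ratios through the Woodbury identity on
  the q×q random-effect cross-product; a fit costs O(n + q³) per
  criterion evaluation. A second model adds the bird's handedness
  class (left/right/neither) as a categorical fixed effect to check
  how much of the intensity repeatability handedness explains.

Numerical details: the Gaussian optimiser starts from moment-based
variance-ratio guesses, runs bounded L-BFGS-B, and polishes with a few
central-difference Newton steps (forward-difference gradients limit
L-BFGS-B to ~1e-5 in the ratios; the polish restores ~1e-8, enough to
match the balanced one-way ANOVA closed form to 1e-6). Convergence is
certified by first-order conditions (projected gradient at boundary
estimates). A constant response returns the degenerate all-zero fit,
flagged, with R undefined. Estimated variances may legitimately sit on
the zero boundary.

Inference:

* **Parametric bootstrap** (default 1000 replicates): responses are
  simulated from the fitted model, refitted, and R collected; reported
  are the SD and the 2.5/97.5 percentile interval. More than 10%
  failed replicates triggers a warning with the effective count.
* **Permutation test** (default 1000 permutations): the focal grouping
  labels are shuffled across observations, breaking individual
  structure while preserving the marginal response;
  p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm), so the smallest
  attainable p is 1/(n_perm + 1).
* **Likelihood-ratio test** (cross-check): the focal random effect is
  dropped and 2Δloglik referred to the 50:50 χ²₀/χ²₁ mixture
  appropriate for one variance component on the boundary; identical
  models give statistic 0 and p = 1. Both p-values are reported.

All resampling seeds are mandatory inputs recorded in output metadata;
identical config + seed reproduces outputs bit-for-bit.

## Synthetic data

The generator works at two levels so the statistics are testable
without signal processing and the signal chain end-to-end:

* **Records**: per-bird left-bias b_i ~ N(0, σ²_id,logit), shared
  per-day effects d_j ~ N(0, σ²_date,logit), dive direction ~
  Bernoulli(logistic(b_i + d_j)); roll angle = ±max(μ + a_i + ε, 1°)
  with the sign tied to the drawn direction, a_i ~ N(0, σ²_id,angle),
  ε ~ N(0, σ²_resid,angle). The 1° magnitude floor keeps angle sign
  and direction mutually consistent, the convention the pipeline
  assumes. Ground truth returns every latent draw and the implied
  repeatabilities (σ²_id,logit/(σ²_id,logit + σ²_date,logit + π²/3)
  for direction; σ²_id,angle/(σ²_id,angle + σ²_resid,angle) for
  intensity).
* **Traces**: flapping flight (surge ≈ +0.3 ± 0.2 g, level posture),
  a 1.5-s roll ramp followed by a 5-s held pre-dive roll at the drawn
  angle with surge dropped to a glide, then a 3-s plunge with surge
  mean −2 g and SD 3 g — clearing both detection thresholds by well
  over the 20% construction margin. Day j's dives sit inside elapsed
  seconds [j·86400, (j+1)·86400), so detected events carry the correct
  day grouping; sampling is only rendered around activity.

Default population parameters are the study-scale conditions the
package targets: 51 birds, 1–6 tag-days each, ~13 dives per bird-day,
σ²_id,logit = 34 and σ²_date,logit = 1.4 (implied direction
repeatability ≈ 0.88 individual, ≈ 0.04 day), mean roll intensity 25°
with bird-level SD 12° and within-bird SD 7° (implied intensity
repeatability ≈ 0.75).

What the traces do *not* emulate: hydrodynamic impact transients,
pitch changes, depth-dependent signal, recording dropouts mid-dive,
tag slippage, or any dependence of dive rate on foraging success.
Passing the end-to-end tests therefore demonstrates that the
*algorithmic chain* recovers known structure through realistic signal
regimes — not that the detector is robust to every failure mode of
field data.

Known systematic effects visible in the synthetic chain, at realistic
size: detection latency shifts the scored window ~0.3–0.7 s into the
plunge, shrinking measured intensity by a few percent and attenuating
the recovered intensity repeatability relative to the generating value
(≈ 0.65 recovered vs 0.75 generated at study scale); the recovered
direction repeatability is within ±0.1 of the generating latent value.

## Problem sizes in tests and the acceptance script

Parameter-recovery suites use 40 replicate datasets of 50 birds × ~40
dives per true R ∈ {0.2, 0.5, 0.8}; permutation size checks use 50
null datasets of 20 birds × 10 dives with 59 permutations each;
bootstrap coverage uses 25 datasets × 79 replicates. The end-to-end
study uses 30 birds. The acceptance script simulates the full 51-bird
study and uses 200 bootstrap and 200 permutation replicates. These
sizes keep Monte-Carlo error comfortably inside the asserted
tolerances while completing quickly on a single CPU.

## Limitations

* Repeatability here is intercept-only (agreement across contexts);
  random-slope or multivariate extensions are out of scope.
* The binomial fitter is Laplace-only for crossed designs; adaptive
  quadrature is available as an oracle route only in the
  single-factor case.
* Calendar-day assignment uses the deployment's single configured
  civil-time offset; a dive is credited to the day its start falls in,
  including trips that cross midnight.
* The power analysis implements the standard Cohen's-h machinery; it
  intentionally does not attempt to reproduce any particular published
  post-hoc power number whose inputs are not reconstructible.
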