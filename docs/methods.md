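# Methods

`scpflow` re-creates, as a tested pipeline, the statistical analysis of a
slow-cortical-potential (SCP) neurofeedback trial in adolescents with
autism spectrum disorder: EEG-derived outcome tables, competing linear and
quadratic Bayesian multilevel models, WAIC model comparison, and the
posterior functionals used to summarise treatment effects (improvement
scores, task differentiation, evidence ratios).  Because the underlying
participant data are not public, a first-class synthetic-data generator
reproduces the study design with known ground truth, and every stage of
the pipeline is validated against it.

## Study design being emulated

Two arms: an experimental group (n = 21) receiving 24 SCP neurofeedback
sessions and a control group (n = 20) receiving treatment as usual.  Each
session has 120 regulation trials in three blocks — feedback 1, transfer
(no on-screen feedback), feedback 2 — and two tasks: produce cortical
negativity or positivity relative to a pre-trial baseline.  Phase 1
(sessions 1–12) uses a 50/50 negativity/positivity ratio; phase 2
(sessions 13–24) uses 80/20.  EEG is sampled at 128 Hz at FCz; each trial
consists of a 2 s baseline window and an 8 s trial window.  Both arms
complete the Social Responsiveness Scale (SRS; total plus five subscales)
on six occasions.

## Synthetic-data generator

The generator is the package's stand-in for the study conditions, not a
tuning dial: its defaults were calibrated once to the reported effect
magnitudes and are used unchanged by all validation studies.

**SCP feature tables.**  One row per participant × session × condition ×
task.  The outcome is a fixed quadratic-in-session surface plus
correlated person-specific deviations plus Gaussian noise.  The fixed
surface is parameterised through anchor values of *differentiation* (the
signed negativity-minus-positivity contrast): −2.28 µV at session 1
rising to −5.54 µV at session 24 in feedback 1, −3.77 → −4.01 µV in
transfer, −4.08 → −3.94 µV in feedback 2, with mild curvature
(−0.004…−0.002 µV per centered-session², chosen so the learning effect
accelerates late, as session-mean curves suggest).  The negativity-task
trajectory declines with slope −0.06 µV/session and curvature
−0.006 µV/session².  These anchors are projected exactly onto the
18-column treatment-coded design of the quadratic model, so generator
truth and model fit share one coefficient basis.  Variance components:
per-person sds 2.5 µV (intercept), 2.0 (task contrast), 0.08/0.006
(linear/quadratic session terms), 0.05/0.004 (their task interactions),
residual sd 2.5 µV at the cell level (plausible for session averages of
~40 artifact-free epochs); intercept–task correlation 0.2, otherwise
independent.  The quadratic model is by construction the true model, so
WAIC selection between linear and quadratic fits is a meaningful
recovery exercise.

**Raw epochs.**  Each epoch is 1/f ("pink") background noise (power ∝ 1/f
within 1 dB over 0.5–40 Hz; spectrally shaped white noise, sd 10 µV), a
10 Hz oscillation (4 µV), and a linear drift over the trial window only,
whose end magnitude is scaled so that the downstream SCP amplitude (mean
of the last 4 s after baseline correction) equals the ground-truth
surface exactly in the noise-free limit.  A configurable fraction of
epochs (default 5%) receives a large half-sine transient (400 µV, i.e.
≥ 5× a clean epoch's typical peak-to-peak).  Task labels within a block
follow the phase ratio exactly, in shuffled order.  Trial repetition
after online artifacts is not modelled.

**SRS tables.**  Per subscale: quadratic decline `a + b·t̃ + c·t̃²`
(t̃ centered at 3.5) with control slope −0.54/occasion per subscale
(t1−t6 improvement 13.5 total points) and an extra experimental slope
summing to −7.88/5 across subscales, split in proportion to the reported
per-subscale differences in improvement; curvature +0.35 (decline
decelerates).  Per-person intercept/linear/quadratic effects are drawn
from a joint 15-dimensional covariance (exchangeable 0.5 correlation
across subscales × a small within-subscale term correlation), and
subscale residuals are drawn jointly with an exchangeable 0.3
correlation (sd 1.8).  Scores are left continuous by default (the models
assume Gaussian residuals); an optional flag rounds them.

What the generator does *not* emulate: operant-learning dynamics, ocular
artifact topographies, trial repetition, floor/ceiling effects, or
integer questionnaire scoring.  Green validation studies therefore show
that the pipeline recovers what it assumes, not that the assumptions hold
in any particular real dataset.

## Feature extraction

* **Filtering** — zero-phase windowed-sinc FIR (Hamming), odd length,
  applied with exact delay compensation and odd-reflection padding (so
  linear trends pass without edge corners).  The SCP path uses a 2 Hz
  low-pass (transition 2 Hz; stopband ≥ 50 dB); the PSD path a 40 Hz
  low-pass.  The nominal 0.01 Hz high-pass edge is unrealisable on 10 s
  epochs; the low edge is implemented as DC removal (mean subtraction),
  which attenuates the DC component completely and is documented as the
  testable contract.
* **Baseline correction** — subtract the 2 s baseline mean from both
  windows.
* **SCP amplitude** — mean over the last 4 s of the trial window.
  Sample-grid convention: trial window is [0 s, 8 s) sampled at k/rate,
  "last 4 s" are indices 4·rate…8·rate−1 (hence closed forms carry a
  half-sample correction).
* **Artifact rejection** — adaptive per participant × session: epochs
  whose trial peak-to-peak exceeds the group's upper Tukey fence
  (Q3 + 1.5·IQR, type-7 quartiles) are rejected.  This preserves the key
  property of the published adaptive approach (a threshold per
  participant per session rather than a global cutoff) with a far simpler
  statistic; it is *not* a re-implementation of the autoreject algorithm.
* **Multitaper PSD** — DPSS tapers with time-half-bandwidth 4, tapers
  with spectral concentration ≤ 0.9 discarded, adaptive eigenvalue
  weighting (delegated to MNE-Python, the toolchain this processing
  models).  PSD is computed on the filtered, not baseline-corrected,
  trial window; mean removal is implicit in tapering.  Band averages:
  delta [0.5, 4), theta [4, 8), alpha [8, 12] Hz (the top band includes
  its upper edge so the 12 Hz bin is not orphaned).
* **Aggregation and extreme values** — cell means per participant ×
  session × condition × task with epoch counts recorded; Tukey fences
  per outcome across the aggregated table set an `outlier_flag`.
  Flagged rows are dropped from model input, never imputed or altered.

## Models

Four model families, written in a small Wilkinson dialect (treatment
coding; references control / feedback1 / negativity; Session and Time
centered at the midpoint of their observed range *before* squaring —
an affine choice that decorrelates linear and quadratic terms and leaves
predictions invariant):

* SRS total, linear:  `Score ~ Group*Time + (1 + Time | Person)`
* SRS total, quadratic:  `Score ~ Group*Time + Time2 + (1 + Time + Time2 | Person)`
  (the quadratic fixed part enters without a Group interaction,
  mirroring the reported specification)
* SCP/PSD, linear:  `Amplitude ~ Condition*Task*Session + (1 + Session*Task | Person)`
* SCP/PSD, quadratic:  `Amplitude ~ Condition*Task*(Session + Session2) +
  (1 + (Session + Session2)*Task | Person)` — 18 fixed columns
  (3 conditions × 2 tasks × {1, linear, quadratic}), 6 varying terms.

A multivariate variant treats the five SRS subscales as a joint outcome:
subscale-specific fixed coefficients, a free 5×5 residual covariance,
and one joint covariance over all 15 subscale-specific varying effects
(one admissible reading of "correlations between varying effects across
subscales"; a block-diagonal alternative would estimate fewer
parameters).

**Priors.**  Population coefficients: Normal, sd 2.5·sd(y)/sd(x) per
column (intercept: mean ȳ, sd 10·sd(y)).  All variances and covariances:
the hierarchical inverse-Wishart family of Huang & Wand (2013) with
ν = 2, scale 2.5·sd(y) — this gives half-t(2) marginals on every
standard deviation and uniform marginals on correlations, i.e. the
standard weakly-informative choice in a fully conjugate form.

**Sampler.**  A purpose-built blocked Gibbs sampler (pure NumPy):

1. population coefficients drawn from their exact Gaussian conditional
   with the varying effects *integrated out* (per-person Woodbury
   identities on precomputed cross-products), then varying effects from
   their exact Gaussian conditional — removing the β–u autocorrelation
   that plagues naive alternation;
2. conjugate inverse-gamma / inverse-Wishart updates of σ², Σᵤ (and the
   multivariate residual covariance) given the effects;
3. slice-sampling moves on each log variance against the
   varying-effects-marginalized likelihood, with the effects refreshed
   from their exact conditional afterwards.  These collapsed moves break
   the funnel coupling between a variance component and its effects when
   the component is near zero (without them, the quadratic varying sd
   mixes with an effective sample size of single digits).

Defaults: 2 chains × 1000 post-warmup draws after 500 warmup iterations;
chain c uses the spawned seed stream (seed, c), so fits are exactly
reproducible.  Convergence: split-R̂ and bulk ESS per population
parameter, σ and the varying sds (via ArviZ, cross-checked against a
direct formula implementation); a fit is flagged — returned with a
warning state, never discarded — when any R̂ exceeds 1.05 or is
ill-defined (zero-variance chains).  Numerical guards: a relative floor
of 10⁻⁷·var(y) on σ² and a jitter-retry Cholesky keep the sampler
stable on degenerate (noise-free) inputs.

## Derived quantities

* **WAIC** — elpdᵢ = log-mean-exp over draws of the pointwise log
  likelihood minus its sample variance; WAIC = −2·Σ elpdᵢ.  Pointwise
  likelihoods are conditional on the varying effects (one term per
  observation row; per person-occasion vector in the multivariate
  model).
* **Model weights** — exp(−½Δ)/Σ exp(−½Δ) on WAIC differences (the
  plain pseudo-BMA form, without a standard-error regularisation).
* **Mean improvement** — prediction at the first occasion minus the
  last (positive = symptom reduction); **D** — experimental minus
  control improvement.
* **Differentiation** — predicted amplitude under negativity minus
  positivity at a given condition and session.  Implemented *signed*
  (negative = stronger regulation) even where prose says "absolute",
  because all reported values are negative; **differentiation change** —
  last minus first session.
* **Evidence ratios** — p/(1−p) with p the fraction of draws satisfying
  a directional hypothesis; at p ∈ {0, 1} a finite bound set by the draw
  count is reported, never infinity.  Strength labels at Kass–Raftery
  cut points 1 / 3.2 / 10 / 100 (negative / barely worth mentioning /
  substantial / strong / decisive).
* **Credible intervals** — central (equal-tailed) 95% quantile
  intervals throughout.

All derived posteriors are computed draw-wise and are tested to equal a
straight-line recomputation over the raw draws to 1e−12.

## Validation studies and problem sizes

* *Model selection*: 20 replicate SRS datasets at study scale
  (41 participants, 6 occasions, quadratic truth); linear and quadratic
  fits at 2 × 1000 draws; the quadratic model receives the larger WAIC
  weight in ≥ 80% of replicates (in practice its weight is ≈ 1).
* *Coverage*: 20 replicate SCP tables at a reduced 12-participant ×
  12-session scale; 95% CIs of the 18 population coefficients cover the
  generating values in ≥ 90% of the 360 parameter × replicate cells.
  The reduced scale keeps the study cheap while leaving all 18
  coefficients identified.
* Signal-processing closed forms (noise-free drift recovery to 1e−6;
  ≥ 90% of a 10 Hz tone's multitaper power inside the alpha band) and
  brute-force oracle equivalences (WAIC, Tukey fences, band averages,
  evidence-ratio arithmetic) run at small sizes in under a minute.

## Known limitations

* The low filter edge is a DC-removal contract, not a literal 0.01 Hz
  FIR high-pass (impossible on 10 s windows).
* The adaptive artifact rejection is a deliberate simplification of the
  published algorithm (Tukey fence on peak-to-peak per participant ×
  session).
* The multivariate model requires a balanced design (equal occasions per
  person) and grows a 15×15 varying-effect covariance; with 41
  participants that matrix is weakly identified and relies on the
  weakly-informative prior.
* Evidence ratios from finite draws saturate at the draw count; reported
  bounds should be read as "at least".
* Gaussian likelihoods throughout; no integer/ordinal questionnaire
  model, no missing-data machinery (flagged outliers are dropped).
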