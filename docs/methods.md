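# Methods

`breathdm` implements, end to end and with synthetic ground truth, the
analysis of how the respiratory cycle modulates perceptual and affective
decision-making: respiration-belt preprocessing and state labelling, Psi
adaptive thresholding, state-wise behavioural statistics, and a hierarchical
Bayesian drift-diffusion model (DDM) with group-level
inspiration-vs-expiration difference parameters.

## The decision model

Choices and reaction times are modelled as a Wiener diffusion between two
absorbing boundaries.  Evidence starts at `z * a` (with `z` the *relative*
starting point in (0, 1) and `a > 0` the boundary separation), accumulates
with drift `v` and unit diffusion coefficient, and absorption at the upper
boundary (`x = a`) or lower boundary (`x = 0`) triggers the corresponding
response; the observed RT adds a non-decision time `t >= 0` (encoding and
motor latency, in seconds).

The model is *stimulus coded*: the boundaries represent the two response
categories (up/down for random dot motion, happy/angry for face affect) and
each stimulus class gets its own signed drift — two drifts for the motion
task, four (AL, AH, HH, HL: angry/happy at low/high ambiguity) for faces.

The diffusion coefficient is fixed at 1, one of the two common scale
conventions; all parameter magnitudes are to be read on that scale.  `z` is
a fraction of `a`, so its respiratory delta is dimensionless.

The first-passage density uses the standard pair of series expansions
(small-time and large-time) with the truncation lengths chosen per
evaluation for an absolute error below 1e-9, switching to whichever series
needs fewer terms.  The upper-boundary density is obtained from the
lower-boundary form by the reflection `v -> -v`, `z -> 1 - z`.  The
upper-boundary absorption probability has the closed form

    P(upper) = (1 - exp(-2 v a z)) / (1 - exp(-2 v a)),   P(upper) = z when v = 0,

which the test suite verifies against brute-force path simulation (an early
candidate form with `exp(2va(1-z))` in the denominator disagreed with
simulation and was discarded).

A brute-force Euler–Maruyama simulator (vectorised over paths, boundary
check each step, 20 s censoring cap) serves as the independent oracle for
the analytic kernel and as the engine for sessions and posterior predictive
checks.  Euler–Maruyama overshoots absorbing boundaries by about
`0.58 * sqrt(dt)` per boundary, which inflates fitted `a` slightly and
perturbs RT shapes; synthetic cohorts used in recovery and calibration
experiments are therefore generated at `dt = 2e-4` (the inflation cancels in
the inspiration-minus-expiration deltas, which a large-n maximum-likelihood
experiment confirmed are unbiased at either step size).

## Respiratory states in the model

Respiration enters as additive group-level fixed effects: expiration is the
reference state, and on inspiration-labelled trials every parameter becomes
`theta + delta_theta`.  One delta per parameter is shared across subjects
(no subject-level delta variance), giving 5 deltas for the motion model and
7 for the face model.  The synthetic-data generator ties the modulation to
the state at *stimulus onset*; this is a generator convention — the analysis
supports labelling trials by onset or by response, and which grouping the
fit conditions on is an explicit configuration axis.

## Hierarchy, priors, sampling

Subject-level base parameters are partially pooled through group normals
`theta_s ~ N(mu, sigma)` per parameter.  Priors are flat: wide uniforms with
bounds `v, delta_v in [-10, 10]`, `a in (0.05, 5]`, `delta_a in [-2, 2]`,
`z in (0.02, 0.98)`, `delta_z in [-0.5, 0.5]`, `t in [0, 1] s`,
`delta_t in [-0.5, 0.5]`, group sds uniform on (0, 3].  These leave
negligible posterior mass at the bounds for data on the scales this design
produces.  Subject-level normals are evaluated without truncation
renormalisation (out-of-support proposals are simply rejected); with the
above bounds the truncated mass is negligible.

Sampling is adaptive Metropolis-within-Gibbs:

* component-wise random-walk updates of each subject's parameters (drift
  updates touch only that stimulus class's trials);
* Gibbs draws for the group means (truncated normal, flat prior);
* log-scale random-walk updates for group sds (with the Jacobian term);
* component-wise random-walk updates for the deltas, whose likelihood only
  involves inspiration-labelled trials;
* two joint reparameterisation moves per parameter: a *translation* that
  shifts the whole subject column together with its group mean (the
  subject-prior terms cancel, so only the likelihood decides), and a
  *scale* move that contracts or expands the subject deviations around the
  mean together with the group sd (with the appropriate Jacobian).  These
  break the strong coupling between group-level and subject-level
  parameters that otherwise dominates group-mean and group-sd
  autocorrelation.

Proposal scales adapt toward ~35 % acceptance in windows of 25 iterations
during burn-in only, preserving detailed balance afterwards.  Because the
group and delta blocks are cheap relative to the subject sweep, they are
repeated `group_reps` times per iteration (default 4), which substantially
reduces group-level autocorrelation.  Chains start from moment-based values
(non-decision time at 0.9x the subject's fastest RT, drifts from the
logistic transform of choice fractions, deltas at zero) with per-chain
jitter.  Any proposal that would make a trial's RT fall at or below the
effective non-decision time receives -inf likelihood and is rejected; there
is no ad-hoc truncation.  The likelihood kernel is a numba-compiled scalar
loop over trials, cross-checked in the tests against the vectorised density.

Two sampling profiles are provided: the full design (4 chains x 10,000
samples, burn-in 2,000, thin 2) and a reduced desk profile (4 x 3,000,
burn-in 600, thin 2) used throughout the test suite; the package's own
convergence experiments run at the desk profile, which reaches group-level
Gelman-Rubin statistics below 1.02 on 10-subject cohorts.

Convergence uses the Gelman-Rubin potential scale reduction
`R = sqrt(((n-1)/n W + B/n) / W)` per parameter at the conventional 1.02
threshold.  Posterior predictive checks redraw joint posterior samples,
simulate datasets with the observed per-subject/class/state trial counts
(100 datasets by default), and summarise signed-RT histograms
(lower-boundary responses as negative RTs).

Reported quantities per delta: the 95 % highest posterior density interval
(shortest contiguous interval by a sorted-sample sliding window; ties go to
the lowest start) and the two-sided Bayesian P, `2 * min(P(delta > 0),
P(delta < 0))`, floored at `2/n` so Monte-Carlo runs never report exactly
zero; P < 0.05 is starred.

## Psi adaptive thresholding

The Psi staircase maintains a grid posterior over psychometric threshold
`alpha` and slope `beta` and presents, each trial, the intensity minimising
the expected posterior entropy averaged over the two possible responses
(ties broken to the lowest intensity index for exact replay).  The
psychometric family is a cumulative normal core with fixed asymptotes,

    psi(x) = gamma + (1 - gamma - lambda) * Phi((x - alpha) / beta),

with `gamma` the lower asymptote and `lambda` the lapse rate; `beta` is the
SD of the core (larger = shallower).  The original software's exact family
is not printed, so this is a documented stand-in; all threshold experiments
here use self-consistent simulated observers, so no result depends on
matching that software bit-for-bit.

Two presets mirror the printed task configurations.  Motion (RDM): intensity
(coherence) grid 0–1 in steps of 0.01, threshold grid 0–0.5 in 0.01, slope
grid 0.01–0.2 in 0.1 (two grid points, as printed), `gamma = 0.5`
(two-alternative task), `lambda = 0.05`.  Faces (FAD): intensity and
threshold grids 0–200 in steps of 1 (201 morph levels, 0.5 %-happy steps),
slope grid 0.001–50 in 1, `gamma = 0`, `lambda = 0.02`.  "Guess rate" is
interpreted as the lapse (upper-asymptote shortfall) and "expected minimum"
as the lower asymptote, which is the only reading that fits both tasks.

Thresholds are read from the psychometric function evaluated at the
posterior-mean `(alpha, beta)` by monotone interpolation on the intensity
grid: the 75 %-correct coherence for motion, the point of subjective
equality (50 % 'happy') for faces, and the four face test levels at
35/45/55/65 % 'happy' (AL/AH/HH/HL).  A read-out based on the posterior-
averaged (predictive) function was measured to behave identically on this
design.  Missed trials are repeated at the same intensity without a
posterior update.

## Behavioural statistics

Exclusions: missed trials, RTs under 100 ms, and trials labelled as
respiratory transitions or unlabelled; an exclusion ledger accounts for
every presented trial.  Motion-task response bias uses the signal-detection
criterion `c = -[Phi^-1(H) + Phi^-1(F)] / 2` (H, F the 'up' response rates
to upward and downward stimuli); proportions of exactly 0 or 1 are adjusted
by the 1/(2N) rule before the quantile so `c` stays finite, and subjects
with `|c| > 0.6` are flagged for exclusion from motion analyses.  State-wise
summaries give hit rate (motion) or proportion 'happy' (faces) and the
median RT (midpoint convention), per subject, state and locking.  Group
comparisons are two-sided paired t-tests with a JZS Bayes factor (Cauchy
prior scale sqrt(2)/2), computed via pingouin and cross-checked in the tests
against direct quadrature of the Zellner–Siow integral.  No multiplicity
correction is applied; each domain x locking x measure is tested separately.
Circular respiratory phase maps inspiration onto [-pi, 0) and expiration
onto [0, pi) by linear interpolation within each half-cycle; an eight-bin
phase summary supports phase-resolved descriptives.

## What the synthetic data emulates — and what it does not

The generator produces: quasi-periodic breathing (log-normal cycle durations
around a 4 s mean with CV 0.15, piecewise half-cosine waveform with the
inspiratory rise occupying 40 % of the cycle, Gaussian sensor noise with
sd 0.05 of the unit amplitude, 10 Hz sampling); schedules of 4 blocks x 80
trials with class balance inside each aligned set of 10 (motion) or 8
(faces), 400 ms stimuli, response windows to 2,000 ms past offset and
inter-trial intervals uniform on 500–2,500 ms; and choices/RTs from the DDM
with state modulation at onset.  Default decision parameters (drifts ~2.2,
`a ~ 1.4`, `z ~ 0.5`, `t ~ 0.35 s`, with between-subject jitter) give
median RTs around 0.6–0.8 s and ~75 % accuracy, typical of near-threshold
designs; breathing defaults correspond to ~15 cycles/min with expiration
longer than inspiration.

It does **not** emulate: movement artefacts (annotations are accepted as
input, matching manual practice), amplitude/volume variation or sighs,
respiratory entrainment to stimuli (the ITI jitter exists to prevent it),
drifting performance from fatigue, lapses in the decision process (no
contaminant mixture), or inter-trial parameter variability (sv, sz, st are
deliberately absent; the likelihood is the plain 4-parameter Wiener form).
Passing tests therefore demonstrate correctness of the estimation machinery
under the stated generative assumptions, not robustness to every feature of
real belt data.

## Numerical and design choices

* Zero-phase (forward-backward) Butterworth filtering, because extremum
  *timing* is the quantity of interest; a causal pass would bias peaks late.
  The attenuation of the 5th-order, 1 Hz low-pass is therefore applied
  twice.
* Peak detection on the z-scored filtered signal with topographic prominence
  >= 0.2, minimum separation 10 samples, width >= 2 samples at half
  prominence (widths/distances in samples); troughs are the minima between
  consecutive peaks plus a leading trough.
* "Exactly at a peak or trough" is resolved at sample resolution: an event
  whose rounded sample index equals an extremum's index is a transition.
  At 10 Hz and ~4 s cycles this labels roughly 5 % of events as
  transitions, which the tests use as a sanity band.
* Segments are half-open `[start, end)`, 0-based sample indexing, seconds
  internally; trial tables carry milliseconds and are converted at the
  module boundary.
* Every stochastic operation takes an explicit integer seed (or Generator);
  chains and sessions are bit-reproducible given the seed.
* Missed trials carry NaN RT and a `missed` flag; nothing is dropped
  silently at generation.

## Problem sizes in the test suite

The suite favours a small number of deep, statistically calibrated checks.
The hierarchical-fit experiments run at reduced scale chosen by a pilot
power analysis: convergence on a 10-subject x 160-trial cohort at the desk
profile; planted-effect recovery (`delta_a = -0.04`, `delta_z = +0.014`,
the signs of the motion and face findings respectively) over 10 replicates
of 8 subjects x 160 trials, asserting sign recovery of the
mean-over-replicates posterior means and >= 9/10 HPDI coverage per delta;
null calibration over 4 zero-delta fits (20 two-sided tests, bounded by the
99.7 % binomial band at the nominal 5 % rate) plus the t-test type-I check
at 1,000 replicates.  The Wiener kernel is validated against one million
Euler–Maruyama paths at `dt = 1e-4`.  Recovery experiments condition on the
generator's true onset states; the measured disagreement between detected
and true states on default-noise traces is ~1 %, and labelling fidelity has
its own dedicated checks.

## Known limitations

* The sampler is random-walk based; posteriors with strong subject-level
  correlations (e.g. `a` with `t`) mix more slowly than a gradient-based
  sampler would, which is why the desk profile repeats the group blocks.
* Group deltas are fixed effects; between-subject variability in the
  respiratory effect is not modelled and would be absorbed into residual
  noise.
* The Psi implementation is the classic grid method; adaptive lapse
  estimation and marginal-Psi variants are out of scope.
* Binary state analysis only: continuous-phase regression DDMs are not
  implemented (the circular phase is provided for descriptives).
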