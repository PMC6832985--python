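# Methods

This note records the models behind each stage of the pipeline, the
parameters that matter, what the synthetic generators do and do not
emulate, and the design choices made where the published descriptions of
these algorithms leave the implementation open.

## Coordinate transform and preprocessing

The sensor is adhered at L5 with its y axis nominally vertical, z
posterior and x lateral; small mounting tilts are unavoidable. The tilt
correction is the standard two-rotation small-angle scheme driven by
`theta_x = arcsin(mean a_x)` and `theta_z = arcsin(mean a_z)`: over a long
window dynamic accelerations average to zero, leaving gravity as the
orientation reference. By default the mean is taken over the full annotated
trial; a static-window override is available. The approximation degrades
quadratically with tilt — for tilts up to 10° the residual gravity leakage
after correction stays below 0.05 m/s², which the suite asserts.

Filtering is zero-phase (forward–backward Butterworth, order 4). Causal
filtering would delay contact events by tens of milliseconds and bias every
temporal parameter; zero-phase keeps event times aligned at the cost of
being non-causal, which is irrelevant offline. Cutoffs: 10 Hz for walking
accelerations, 2 Hz for the yaw used in left/right designation. The
gyro-to-pitch/yaw axis mapping and its signs are configuration
(`PipelineConfig.gyro_*`): the device's axis polarity cannot be recovered
from the data, and the side labels are therefore abstract {A, B} with a
config flag mapping them to {left, right}.

Timestamps jitter around the nominal 31.25 Hz, so every trial is first
linearly interpolated onto a uniform grid; all algorithms are parameterised
by the actual rate.

## Gait-event detection

The contact detector follows the trunk-accelerometry wavelet scheme: the
gravity-free, 10 Hz low-passed vertical acceleration is cumulatively
integrated (trapezoid) and smooth-differentiated by a single-scale CWT with
the first Gaussian derivative; local minima of that output are IC
candidates. A second CWT differentiation with the Mexican hat yields EC
candidates as local maxima. The raw correlation sign of the odd gaus1
kernel is kept (it approximates −d/dt), which is the convention under which
minima coincide with the upward heel-strike acceleration peaks.

Numerical choices:

* **Scale selection.** The wavelet scale is `Fc * fs / f_dom`, with Fc the
  wavelet centre frequency (0.2 for gaus1, 0.3 for gaus2) and `f_dom` the
  dominant frequency of the window in 0.5–5 Hz. The strategy is pluggable.
  For windows too short for a stable spectrum (turning intervals), the
  caller passes the step frequency estimated from the pooled walking
  phases.
* **Extremum neighbourhood.** An IC/EC extremum must dominate a
  neighbourhood of 0.35 / f_dom seconds. This keeps exactly one extremum
  per step at any cadence in the physiological range while rejecting
  ripples much faster than the gait rhythm; with a fixed few-sample
  neighbourhood, near-flat stretches of signal would spawn noise-driven
  candidates.
* **Pruning.** EC candidates at or below 20 % of the mean peak magnitude
  are dropped (this relative rule, like the CWT extrema, makes event times
  invariant to overall amplitude scaling). IC pruning is greedy left to
  right: the earliest IC is trusted and any later IC whose lag from the
  previous retained IC falls outside [0.25, 2.25] s is discarded. Events
  within 0.25 s of a window edge are removed (wavelet edge effects).
* The stance-time definition pairs `t_EC(i+1)` with `t_IC(i)`; the EC
  list is effectively offset by one event relative to ICs. This is applied
  exactly as defined.

Detection runs per annotated walking window (each 10MWT trial, each
TUG walking or turning phase), never across quiet sitting or standing —
an unthresholded local-minima rule has no meaning on motionless data.

## Step length

The inverted-pendulum model gives `L_hat = 2 sqrt(2 L h − h²)` from the
per-step vertical excursion h of the centre of mass and the sensor-to-
ground distance L. h is the peak-to-trough displacement within each
step interval; the alternative (displacement difference between
consecutive contacts) vanishes for symmetric steps and was rejected.

Displacement comes from double integration of vertical acceleration with
drift removed at each stage by EMD: the integral is decomposed into IMFs
(classic sifting, cubic-spline envelopes through the extrema,
mirror-extended at the edges, Cauchy stopping threshold 0.2, at most 50
sift passes), each component — including the residual, which carries most
of the trend — is scored by a rescaled-range Hurst exponent (log-spaced
windows from 8 samples to n/2), and components with H > 0.8 are removed.
White noise scores near 0.5, trends near 1; 0.8 cleanly separates
oscillatory gait content from drift at these record lengths.

The correction `+ K S` absorbs the rigid-pendulum bias linearly in shoe
size S. **K and S are unit-coupled**: K is fitted by ordinary least squares
against a gold standard with whatever shoe-size unit the cohort recorded,
and only within-cohort consistency matters. The shipped defaults
(K = 1.13 for self-selected, K = 1.50 for fast walking) presume a
metre-scaled shoe size of order 0.09 and are healthy-cohort values that do
not transfer to impaired gait; `imugait calibrate` refits them from a
calibration table.

## Balance features

All 23 per-condition features are computed on the unfiltered gravity-free
AP/ML accelerations of the annotated static window (minimum 5 s). Spectra
are plain one-sided periodograms with the DC bin excluded, mean-subtracted
input and no taper — a rectangular window keeps line spectra exact, and the
sway band of interest (< 5 Hz) is far from the Nyquist edge. F50/F95 use a
1e−9 tolerance on the cumulative-power threshold so exact ties resolve to
the lower frequency. Jerk is aggregated as the RMS of the central-
difference derivative (mean-absolute is selectable); max and mean
acceleration are of the rectified signal; the acceleration path is the
summed absolute first difference, not normalised by duration. Sway velocity
reuses the EMD drift-free integral.

The 95 % ellipse scales the covariance eigenvalues by the chi-square
2-d.o.f. quantile (5.991); the small-sample prediction-ellipse F scaling,
which differs by O(1/n), is selectable. Axis lengths are reported as full
principal-axis lengths matched to the anatomical axis their eigenvector is
closest to, and the angles (degrees — the natural unit for an orientation)
are the acute angles between each eigenvector and its anatomical axis.

## TUG segmentation and features

Sit-to-stand and stand-to-sit are read off the db5 level-5 approximation of
pitch (pass band ≈ 0–0.5 Hz at 31.25 Hz): the first and last peaks of its
magnitude above 30 % of the maximum, at least 1 s apart, are the two
transitions. A transition extremum below 10 deg/s is treated as noise and
segmentation fails loudly. Turns are the two longest intervals where the
level-2 yaw approximation exceeds 15 % of its trial maximum (threshold
configurable; chosen so scripted 45–180° turns segment robustly), ordered
by time, not amplitude. Stage landmark ii sits at each burst's
angular-velocity extremum; i and iii at the flanking 10 %-amplitude
crossings (turns: the interval edges). Walking phases fill the two gaps.

Per-phase features follow the stage windows exactly: ranges, means,
medians, SDs and maxima of pitch velocity for the transitions; yaw
magnitude (sign-flip invariant) for the turns; mean angular acceleration
over a stage is the net velocity change divided by the stage duration.
Walk features pool both walking phases; step counting inside a turn counts
ICs strictly inside the turn interval. The registry keeps all 43 TUG
features (13 + 13 transitions, 5 + 5 turns, 7 walk); a strict mode drops
the walk-phase duration, giving a reduced 183-feature variant.

## The synthetic generators

The generators exist because no public recordings accompany the
algorithms; they emulate the battery with exact ground truth.

* `gen_walk` builds the vertical CoM displacement as a train of sin²
  arches — one per step interval, height h per step (alternating ±asym),
  vanishing with zero slope at every programmed contact — entered and left
  through C² quintic blends whose end curvature matches the adjacent arch,
  so the analytic second derivative (the emitted acceleration) is
  continuous and double-integrates back to the displacement (verified at
  0.3 % RMS at 125 Hz; at 31.25 Hz the discretisation of the piecewise
  construction dominates). A Ricker-shaped transient at each contact
  mimics heel-strike morphology without disturbing the displacement (its
  first two moments vanish). Yaw oscillates at half the step frequency,
  phase-locked to the stepping side; gravity and a programmed static tilt
  are added back in the sensor frame, plus white Gaussian noise
  (0.08 m/s², a realistic accelerometer noise floor). Contacts are snapped
  to the sample grid so truth is exact in samples. Defaults emulate a
  self-selected-speed walk: 1.8 steps/s cadence, 5 cm CoM excursion.
* `gen_sway` produces band-limited planar Gaussian noise whose *sample*
  covariance is driven exactly to the programmed matrix, so ellipse
  features have closed-form expectations.
* `gen_tug` scripts Hann-shaped pitch bursts for the transitions and yaw
  bursts for the turns, with walking segments built by the same arch
  model. Ground-truth landmarks use the movement-onset convention (the
  fractional-peak crossing matching the segmentation's definition), and
  the first post-transition step is placed relative to the *smoothed*
  transition offset — the observable end of standing up — with contacts
  kept at least 0.35 s clear of every phase boundary, as a subject's steps
  are when the phases are well separated.
* `gen_session` assembles the full battery (3 + 3 ten-metre walks, five
  balance conditions with increasing sway magnitude, two TUG trials, one
  naturalistic circuit).

What the generators do **not** emulate: soft-tissue artifact, sensor
saturation, pink/structured noise (a pink-noise option exists for
robustness experiments but is off by default), pathological gait
(shuffling, non-alternating steps, festination), turns without steps, and
the kinematic coupling between channels of a real body. Passing tests
therefore demonstrate algorithmic correctness under the stated signal
model — clean quasi-periodic gait at moderate cadence with realistic noise
floors — not clinical-grade accuracy on impaired populations. In
particular, step length on real data is known to be the least accurate
output of this family of methods, and the shipped K constants are
cohort-specific.

Problem sizes used by the default suite and the acceptance script — 20–30
steps per walking trial, 30 s balance windows, 50 randomised TUG trials,
10⁵-sample ellipse checks — were chosen as the smallest sizes at which the
estimators' sampling error is comfortably below the asserted tolerances.

## Agreement statistics

The ICC is fixed to the two-way random-effects, absolute-agreement,
single-measure form — the standard match for "absolute agreement between
two systems" — computed from the paired ANOVA mean squares; the test suite
cross-checks it against an independent reference implementation. The
Bland–Altman percentage reports the LoA half-width over the grand mean of
the paired averages (the percentage basis is otherwise ambiguous; the
paired-mean basis is symmetric in the two systems). Degenerate inputs
(zero variance) yield missing values rather than exceptions.

## Known limitations

* The EC/stance-time chain is validated structurally (ordering, pairing,
  the swing identity) but not against an independent toe-off ground truth;
  the generator programs contacts, not toe-offs.
* The tilt correction is small-angle; mounting tilts beyond ~15° need a
  proper orientation filter, which is out of scope.
* EMD is empirical: on signals much shorter than four seconds the
  drift/oscillation separation is unreliable, and those windows fall back
  to polynomial detrending (balance sway velocity on short windows).
* The 31.25 Hz rate bounds event-timing resolution at 32 ms; cadences
  above ~2.5 steps/s approach the detector's reliable limit at this rate.
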