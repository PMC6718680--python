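# Methods

This note documents the scientific and numerical choices behind
`alphawatch`: the detector, the moving-window statistics, the
classification layer, and — in most detail — the synthetic cohort
generator that serves as the package's test bed.

## Signals and conventions

All amplitudes are microvolts; all times are seconds from the first
sample, half-open intervals `[start, end)`. The analysis start (start of
induction) is a user input carried as recording metadata (`t0`,
default 0). Four frontal electrodes (Fp1, Fp2, F7, F8) are required;
EDF channel labels are resolved case-insensitively by substring, with an
explicit alias map taking priority.

The detector operates at a 64-Hz working rate: the Daubechies-2
decomposition maps its level-2 detail onto [8, 16] Hz only when the
sampling rate is a power-of-two multiple of 16 Hz, and 64 Hz is the
smallest such rate that retains the full band. Recordings at other rates
are anti-alias resampled first. S_alpha is the time-domain
reconstruction of the selected detail band (all other coefficients
zeroed) so it aligns sample-by-sample with the recording.

## Alpha-suppression detector

The five steps and their constants (swing window w = 1 s; kernel
B = 0.72, t_b = 1 s, eta = 1.96; burst ratio R = 1.4; threshold
T = 0.25; dilation 0.9 s, erosion 1.1 s; two-of-four consensus) are
described in the README. Choices the procedure leaves open:

* **Swing average.** `Amp(t)` divides the summed swing distances by the
  number of swings in the window (a true average); dividing by the
  window width is available via `amp_divisor="window"`.
* **Kernel boundedness.** The burst kernel is implemented with a
  decaying exponential so that it peaks at `1 + B` at `t_b` and relaxes
  back to 1; the unbounded growing variant is selectable
  (`kernel_sign="growth"`) but is not meaningful as an amplifier.
* **One kernel per burst.** Candidate (min, max) pairs of `Amp` whose
  peak does not dominate `Amp` within ±t_b are discarded. On noisy
  envelopes a single recovery flank otherwise yields several micro-pairs
  that all satisfy the R-ratio rule; their stacked kernels inflate the
  running-maximum normalizer for the surrounding two minutes and create
  spurious detections. The rule collapses each rising flank to its final
  crest and leaves genuinely separate bursts untouched.
* **Thresholding operand.** `|S_phi|` crosses zero every half-cycle, so
  the threshold is applied to a 0.25-s centered moving maximum of
  `|S_phi|` (an envelope), normalized by its running maximum over a
  centered 120-s window, truncated at the edges and floored at 1e-6 µV.
  Both window lengths are configurable; an entirely flat signal is one
  full-span suppression.
* **Morphology convention.** Dilation/erosion move each endpoint by the
  stated amount (so a gap up to 1.8 s is bridged and an isolated
  interval shrinks by 0.4 s); a structuring-element convention (half
  those amounts) is selectable.
* **Consensus.** Exact sweep-line over interval endpoints; consensus
  runs shorter than 0.1 s are dropped as single-sample coincidences.
* **State precedence.** Consensus alpha-suppressions are trimmed against
  IES so that αS / IES / alpha+delta partition the recording.

## IES detection and labeling

IES are maximal runs of `|(Fp1 + Fp2)/2| <= 8 µV` lasting at least 1 s,
computed at the native rate on the broadband signal. Runs interrupted by
even a single-sample excursion are not bridged, and no morphology is
applied. A patient is labeled `IES` when the cumulated IES time in the
first 35 min reaches 10 s (a boundary value counts as IES).

## Moving-window statistics

* Proportions use a backward-looking 240-s window stepped every 1 s,
  truncated at the span start and normalized by the effective window
  length, so the three states always sum to 100%.
* First-occurrence times are the earliest instants the αS (resp. IES)
  proportion reaches 5% (inclusive).
* The initial slope `a` is the through-origin least-squares slope of
  P_alpha over the first 10 min, in %/min.
* `F_alpha` counts distinct consensus events by their start time inside
  a centered 50-s window stepped every 10 s, divided by the window
  width in minutes; counting by event midpoint is selectable.
* Per-event amplitudes integrate the rectified alpha-band signal with a
  piecewise-linear (trapezoidal) rule handling fractional endpoints
  exactly. For consensus events the two smallest per-electrode event
  means are averaged: a consensus event is present on at least two
  electrodes, so those two always show the suppression, while an
  electrode on which the event is absent would contribute its full
  alpha rhythm and swamp the suppressed amplitude. Ranking by value
  rather than by detection overlap keeps the estimator free of
  selection effects that vary with event duration. The inter-event
  series A_IaS uses the complement of αS ∪ IES and all four
  electrodes.
* Group averages follow the event-interpolation procedure: each
  patient's event series is linearly interpolated onto a common 1-s
  grid, but only between that patient's first and last event (the
  interpolant is undefined outside); grid points supported by fewer
  than three patients are dropped, since a handful of patients is not a
  group average. Patients with no events are excluded with a warning.
* The saturation fit `y = F_max (1 − exp(−t/tau))` uses multi-start
  nonlinear least squares (tau started at 0.2–10 min, positivity
  bounds); a constant series degenerates to `F_max = const`,
  `tau -> 0`.

## Classification

Nested cross-validation: stratified 5-fold outer splits repeated (20 by
default), 3-fold inner grid search maximizing AUC; features are
z-scored inside each training fold for the logistic model, trees use
raw values; ROC curves are vertically averaged on a 101-point FPR grid;
everything is reproducible from one seed. The coarse grids (logistic C
in 10^-2..10^2; forests with 200/500 trees, depth 2/3/5/unlimited,
minimum leaf 1/3/5) suit cohorts of tens of patients; `FAST_RF_GRID`
drops the forest-size axis, which is irrelevant at n ≈ 30, and is used
by the small-cohort analyses. Feature importance is impurity-based,
normalized to 100% per fold and averaged. Proximity embeddings apply
classical metric scaling to 1 − (shared-leaf fraction). The tuned
classification tree maximizes full-data accuracy over an exhaustive
depth/leaf grid (ties prefer shallower trees); its entropy profile
I_H(L) is the sample-weighted base-2 class entropy of the frontier
holding the internal nodes at depth L plus all leaves above it — the
definition makes I_H nonincreasing in L.

## Synthetic cohorts

### Signal model

Each patient is 35 min of four-channel EEG at 128 Hz:

* **delta**: band-limited Gaussian noise 0.5–5 Hz with power tilted
  toward the low end (second-order low-pass at 2.5 Hz inside the band —
  the 1/f-like shape of cortical slow activity), RMS 15 µV, 40% of the
  variance shared across channels;
* **alpha**: a common 10-Hz carrier with per-channel slow envelopes
  (low-pass 0.1 Hz, depth 0.08, clipped to [0.85, 1.15]), RMS ≈ 10 µV;
* **sensor noise**: white, RMS 2 µV per channel.

Alpha-suppressions replace the alpha component by a residual sinusoid
whose amplitude declines linearly in time (carrying the configured
A_alpha slope); delta persists, matching the definition of αS as a
partial suppression of the [8, 16] Hz band. Events are drawn from an
doubly stochastic (Cox) process: the saturation law
`F_max (1 − exp(−(t − t_on)/tau))` starts after a log-normal onset and
is multiplied by a slow log-normal modulation (σ = 0.45, correlation
time 2 min), then thinned with a 2-s dead time after each event;
durations are log-normal around the group duration law. The modulation
makes events cluster in time, so short-window counts are overdispersed
relative to a Poisson process — the reason the occurrence frequency is
a noisier per-patient predictor than the window-averaged proportion
slope, as the study's univariate results show. Every event is planted
on all four channels and then dropped from at most two of them with
probability 0.15. Each patient carries mean-one log-normal severity
multipliers on rate (σ = 0.18), duration (σ = 0.10) and saturation
speed (σ = 0.35 on tau): real patients differ far more in their
suppression burden than the group means do, and this spread gives the
initial slope `a` its cohort-level distribution. The generator draws
background, alpha-suppression and IES randomness from independent
child streams of the patient seed, so the three components can be
varied without re-randomizing one another.

IES are whole-signal attenuations (×1/18, to ≈ 1 µV RMS) starting after
a log-normal onset, recurring as a Poisson process (0.55/min) with
durations uniform on 8–20 s. Ground-truth IES intervals are defined by
the amplitude rule itself (|Fp1+Fp2|/2 ≤ 8 µV runs ≥ 1 s around each
planted window) — the broadband background crosses ±8 µV at every
zero-crossing, so the planted window edges are not recoverable by any
amplitude criterion, while the amplitude-rule truth is recovered
exactly. Chance flat periods — the background dwelling inside ±8 µV for
a second during an alpha-suppression — count as iso-electric time by
the same rule.

Demographics follow the study cohort's moments (age 52.8 ± 14.5 yr in
18–85, height 167 ± 8 cm, weight 70.2 ± 13.6 kg, MAP drop
28.3 ± 10.6 mmHg) with an age–ΔMAP correlation of 0.55 through a
Gaussian copula. Group age means differ (59.2 vs 48.3 yr), reproducing
the weak demographic signal the study cohort itself shows; height and
weight carry no group information.

### Calibration: the phenotypes target *detected* statistics

The phenotype constants are the published group statistics, and the
generator is calibrated so that the full detect-and-summarize pipeline
*returns* them, not merely plants them. The frozen calibration
constants, measured in seeded closed-loop runs:

* `DUR_DETECTION_BIAS_S = 0.65` — the envelope moving-maximum plus the
  net erosion shorten every detected event by ≈ 0.65 s, so planted
  durations are lengthened by that amount;
* per-phenotype `rate_correction` (1.32 IES / 0.99 noIES) — residual
  losses from imperfect recall and dead-time interaction;
* onset leads (`AS_ONSET_LEAD_MIN = 1.30`, `IES_ONSET_LEAD_MIN = 0.33`)
  — the 5%-of-window criterion crosses threshold well after events
  begin appearing, so planted onsets are advanced;
* `AMP_SLOPE_GAIN = 2.10` — near the band's noise floor the rectified
  mean responds sub-linearly to the planted residual-amplitude decline;
* a 0.968 factor on the maintenance duration — the detector slightly
  inflates the steady-state busy fraction.

Two structural choices resolve tensions inside the published group
numbers. First, a stationary process with the IES group's frequency
plateau (8.3/min) and induction-end durations (≈ 2.6 s) would occupy
~35% of the trace, not the observed steady-state proportion of 18.5%;
the generator therefore lets IES-group durations relax after induction
to the value implied by the steady-state proportion, which also
reproduces the observed overshoot-and-settle time course of P_alpha.
The noIES group honors its duration and frequency values instead, so
its realized steady-state proportion (≈ 6.4%) sits below the published
7.85%. Second, the published between-patient spread of IES onset times
(IQR ≈ 16 min) is incompatible with requiring a 20-patient median
within half a minute of the group value; the generator uses a narrow
onset distribution (log-normal σ = 0.06), trading cohort realism for a
well-defined group median.

### What the generator does not emulate

Artifacts (movement, electro-surgery, ocular), non-stationary carrier
frequency, spindle-like intermittency of real alpha, burst morphology
inside burst-suppression, inter-patient differences in electrode
quality, and any biophysical (neural-mass) dynamics. Passing the
closed-loop checks therefore demonstrates that the detector and
statistics recover the group structure of signals with the *assumed*
spectral content — not detector robustness on clinical recordings,
which would additionally require artifact handling.

## Problem sizes

Cohort analyses use 15 patients per group (and a separate 20-patient
cohort for onset medians) at 35 min and 128 Hz; nested cross-validation
on these cohorts runs 4–5 outer repeats with `FAST_RF_GRID`. These are
the package's default study sizes; all are parameters.

## Known limitations

* The detector's constants are tuned to the 64-Hz working rate; other
  dyadic rates change the band edges and were not calibrated.
* The A_alpha induction slope is the most variance-prone closed-loop
  statistic: at 15 patients its replicate standard deviation is of the
  order of 1 nV/min around the −8.1 nV/min target.
* Exact IES truth equality holds because generator truth and detector
  share the amplitude-rule definition; planted-window boundaries differ
  from it by up to ~0.1 s.
* The morphology bias correction is a constant; for events shorter than
  ~1 s the actual bias is duration-dependent.
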