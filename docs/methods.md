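# Methods

`hemisim` re-implements, offline and testable, a gaze-contingent display
(GCD) that simulates complete homonymous hemianopia in a panoramic static
driving simulator, together with the data-processing pipeline that turns raw
gaze and driving logs into per-scenario scanning and lane-keeping measures
and into the EAB (equal/above/below) within-subject comparison.  This note
documents the models, the numerical choices, and what the synthetic study
generator does and does not emulate.

## Rig model and mask engine

The frontal 180° view is modelled as three flat panels of 3400 × 2720 px,
each tangent to the viewing circle at its center azimuth (−60°, 0°, +60°)
and subtending 60°; the viewer sits at the circle's center.  Azimuth is
signed (negative = left), elevation positive up.  Sectors are half-open —
[−90°, −30°), [−30°, 30°), [30°, 90°] — so every azimuth belongs to exactly
one panel (the right panel owns +30° as a deterministic tie-break).  The
vertical half-angle follows from the pixel aspect ratio,
atan((H/W)·tan 30°) ≈ 24.79°.  Within a panel,

    px_x = W/2 · (1 + tan(az − center)/tan 30°),
    px_y = H/2 · (1 − tan(el)/tan(vertical half-angle)),

with the origin at the top-left corner; anchors stay at fractional pixels.
Gaze arrives as a unit vector from the virtual eye position;
az = atan2(x, z), el = asin(y).  Invalid (zero/non-finite) vectors are
flagged, not raised, so the hold-last-sample policy applies downstream.

Anchor smoothing uses an arithmetic moving average (default window 3
samples ≈ 50 ms at 60 Hz).  A movement exceeding the bypass threshold
(default 10°) relative to the previous output clears the buffer and passes
the newest sample through unsmoothed, so large scans relocate the mask in a
single frame; invalid samples repeat the last output with a `held` flag.
Window length, bypass threshold and fade width are configuration keys: the
deployed system states these mechanisms without numbers, so the defaults
are declared choices.  The occlusion profile is a function of azimuth only
(the mask spans the full panel height): fully opaque on the blind side of
the anchor, linear semitransparent fade of configurable width (default 4°,
interpreted as visual angle, not pixels) across the boundary.  The occluded
field fraction has a closed form (clipped trapezoid) and, with the ramp
fully inside the field, equals the hard-edge value — a conservation
property the tests check against numeric integration.

## Preprocessing

Order is fixed: head-gaze fallback → AOI exclusion → low-pass.  Invalid eye
samples take the head-pose-derived direction (`source='head'`); samples with
neither carry the last usable azimuth (`held`).  Excluded AOIs (blinks,
mirror, media system, other non-driving areas) are flagged, not removed:
gaps advance time and are never interpolated, because interpolation would
fabricate gaze positions inside blinks.  Head-substituted samples are
filtered like eye samples.

The 10 Hz low-pass is zero-phase with gain |H(f)|² = 1/(1 + (f/f_c)^(2n)),
the squared magnitude of an order-n Butterworth (n = 2 by default), applied
in the frequency domain on reflection-padded segments.  This realises the
forward–backward Butterworth magnitude exactly — at 60 Hz sampling a
bilinear discrete design would warp the response near Nyquist (a 20 Hz tone
would be attenuated to ~0.012 of its amplitude instead of the analytic
1/17) — and has no phase lag, so fixation onsets are unbiased.  Filtering
is applied per contiguous unexcluded segment; segments under 5 samples pass
through.  Offline analysis tolerates the non-causality.

## Event detection

Thresholds follow DIN EN ISO 15007-style practice: a fixation is a window
of ≥ 120 ms in which the horizontal position spans ≤ 2° *and* every sample
speed stays below 30°/s; the window extends rightward while both conditions
hold (an I-DT-style dispersion-duration detector with a conjunctive
velocity check — the minimal reading of both stated rules).  Saccades are
maximal runs of samples at ≥ 90°/s; amplitude is the horizontal
displacement between the run's first and last sample, with no onset
back-extension.  Speeds come from central differences on the filtered
azimuth (one-sided at segment ends).  Samples between 30 and 90°/s belong
to neither class.  Dispersion is measured on the horizontal channel only.
Durations are sample-count durations (n samples ↦ n/fs), so one second of
steady gaze is a 1.0 s fixation.  Excluded samples terminate events.

## Scenario metrics

The deceleration phase runs from the first braking sample within 100 m of
the intersection to the zebra crossing (distance 0); if no braking occurs
in that range the window starts at 41.76 m, the typical deceleration onset
3 s before an intersection at 50 km/h.  (The stored constant is 41.76 m,
although 3 s × 50 km/h works out to 41.67 m; the published value wins and
the discrepancy is noted here.)  Gaze (60 Hz) and driving (240 Hz) streams
are aligned by timestamp; the window is defined on driving time.  Sample
statistics (gaze variance/mean/min/max, lane mean/variance/crossings) use
the closed interval [t_start, t_end]; events are detected on the full
stream and attributed to the window by onset, so window edges do not
truncate event durations.

Lane position is the offset to the ideal lane center in cm (positive =
right); variance is the sample variance (cm² by default, configurable).
A lane crossing is an entry into |offset| > 85 cm — the boundary is not
part of the published procedure; 85 cm = (3.5 m lane − 1.8 m vehicle)/2 is
a config key.  Hemifield fixation counts and mean durations cover fixations
beyond the central 10° (|mean azimuth| > 5°); directional saccade
amplitudes average saccades whose endpoint lies more than 5° into the
corresponding periphery.  First-scan side is the earliest sample at ≥ 30°
(or 45°) eccentricity; missing large scans use the 45° criterion per side.
Percentages are 100·k/K rounded half-up to two decimals.

## EAB analysis

For each measure, subject and intersection type, the reference band is half
the interquartile range of all participants' normal-vision (NV) values in
that intersection type (the subject's own value included), centered on the
subject's NV value; the impaired-condition value is `equal` inside the
closed band, `above`/`below` outside.  Quartiles use linear interpolation
of order statistics (type 7) — the estimator is a convention, so it is
configurable, and the tests guard it against an independently hand-rolled
oracle.  The blind-versus-seeing variant re-centers the band on the
subject's seeing-side fixation count with the half-IQR of the seeing-side
sample; this construction is an interpretation (the original description
is brief) and is isolated in one function.  Classifications are
translation- and scale-equivariant; a zero-IQR band degenerates to exact
three-way comparison.  Lane-position classes are mapped to buffers: under
left-sided loss a value above the band means the vehicle moved right, i.e.
a buffer on the blind side; mirrored under right-sided loss.

## Synthetic study generator

The generator emulates 15 subjects × 3 vision conditions (NV, LHH, RHH) ×
3 intersection maneuvers (SCI, LTI, RTI).  Driving: constant 50 km/h
approach from 150 m, brake onset drawn uniformly from 25–95 m (5 % beyond
100 m, 5 % no braking — matching the occurrence of fallback windows),
constant deceleration to ~7 km/h at the crossing; lane offset is a
stationary AR(1) process (φ = 0.999 at 240 Hz, stationary SD ≈ 12 cm)
around −15 cm, with rare planted boundary excursions (p ≈ 0.045, matching
6 crossings in 132 scenarios) placed inside the deceleration window.
The resulting phase durations average ≈ 8 s.

Scanning: fixation durations are lognormal; positions follow a
mean-reverting random walk around the condition's gaze bias with step sizes
drawn from a lower-truncated normal (≥ 8°, location adjusted so the mean
equals the amplitude parameter).  Per scenario, a ≥ 45° excursion to each
side is scheduled with condition-dependent probability — implemented as a
staircase of ordinary-amplitude saccades out to ≥ 50° and back, so the
amplitude distribution is not distorted.  Condition defaults take their
directions and scales from the published descriptive tables (longer
fixations ≈ 335 ms and smaller amplitudes ≈ 19.6° under LHH, rightward
bias ≈ +3.4° under RHH, more missing scans under LHH); the per-side
excursion probabilities are set to one minus the published missing-scan
rates.  These magnitudes are generator parameters, not reproduction
targets.  Saccade transitions are raised-cosine position profiles with
peak velocity well above the 90°/s threshold (≥ 250°/s, scaling with
amplitude) rather than a full main-sequence model — enough to exercise the
detection rule.  Corruption channels: 0.3° Gaussian position noise, blinks
(~10/min) modelled as brief occlusions between events, tracker dropouts
(2 % of samples) concentrated during large gaze movements — which is where
in-vehicle trackers actually lose the eyes — with a 2 Hz-smoothed head-gaze
channel as fallback, and occasional mirror glances exercising AOI
exclusion.

**Detector-native planting.**  A 60 Hz-sampled, 10 Hz-filtered saccade is
an attenuated image of the underlying step: threshold-crossing endpoints
read only part of the displacement, and the velocity check shaves samples
off flanking fixations.  Both distortions are deterministic properties of
the measurement chain, so the generator calibrates them at run time by
pushing its own transition template (and, for the stochastic corruption
channels, fixed-seed probe streams) through the actual filter and
detectors, then plants inflated position steps and extended plateaus so
that the *expected detector reading* equals the drawn parameter.  Planted
amplitudes and durations therefore denote detector-level quantities.
Similarly, because the pipeline applies its eccentricity thresholds to the
filtered signal (whose slight overshoot near large saccades is part of the
measurement), the categorical scan truths are defined on the noise-free
filtered trace; and since `gaze_bias` *is* the mean eccentricity, each
realized trace is recentered so its window mean equals the parameter
exactly.  With all corruption disabled, every planted categorical truth
(first-scan sides, missing-scan flags, lane crossings, window triggers,
event counts) is recovered exactly; under the default noisy profiles the
pipeline recovers fixation-duration, saccade-amplitude and gaze-bias
parameters within three standard errors.

What the generator does *not* emulate: vertical scanning structure, smooth
pursuit of moving traffic, vergence, saccadic main-sequence kinematics,
head-eye coordination dynamics, learning/compensation over time, and any
coupling between gaze and steering.  Passing tests therefore demonstrate
that the pipeline measures what was planted under the stated statistical
model — not that the model reproduces human scanning in full.

## Problem sizes and seeds

The test suite runs the full 15-subject study (135 scenarios, ~8 s windows)
once noisy and once noise-free, the detector-vs-oracle comparison on 1000
random plateau-and-transition traces, and the mask round-trip on 100 000
azimuths; the acceptance script repeats these at slightly smaller trace
counts.  All randomness flows through explicit seeds (`numpy`
`SeedSequence` spawning per scenario), so reruns are bit-identical.

## Known limitations

* The published lane-position variances (0.66–2.16) are not reconcilable
  with cm-scale offsets, and some printed first-scan percentages are
  internally inconsistent; neither is treated as a reproducible quantity —
  the variance unit is a config key.
* The real-time SmartEye/SILAB integration, projector rendering and
  rear-view displays are out of scope; the mask engine replays logs
  offline.
* Inferential statistics (mixed-model ANOVA, post-hoc tests) are out of
  scope: the metrics module emits model-ready tables.
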