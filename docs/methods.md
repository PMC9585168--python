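# Methods

## The measurement model

A larval zebrafish ventricle in a single-channel fluorescence movie is
treated as a single bright region on a dark background. Per frame, the
pipeline measures:

- **area** — foreground pixel count × pixel_size², in µm²;
- **long/short axes** — the *full* major/minor axis lengths of the ellipse
  with the same normalized second central moments as the segmented region
  (4·√eigenvalue of the pixel-coordinate covariance), in µm.

The six cardiac-function indicators follow from phase-averaged geometry.
Volumes use the prolate-spheroid model `V = (4/3)π(a/2)(b/2)² = πab²/6`
with `a`, `b` full axis lengths; for `a = b = d` this is the sphere volume
`πd³/6`. All fractions (FAC, FS, EF) are carried dimensionless in the code
and reports; percent is display formatting only. This convention is forced
by the AHFI arithmetic: the published activity thresholds (1.0 / 0.6 /
−0.5) and reference-compound scores near 0.7 are consistent only with
summed fractional recovery scores.

## Segmentation

Per frame: global Otsu threshold (or a fixed intensity cut), morphological
closing (disk, radius 2 px) to heal boundary holes, restriction to the
largest connected component, and a minimum-size gate (50 px). A flat frame
or one with no sufficiently large component yields an *invalid* frame, not
an exception; downstream analysis interpolates isolated invalid frames and
refuses sequences with < 80% valid frames.

The largest component is assumed to be the ventricle. This holds for the
single-chamber simulator; on real two-chamber recordings the atrium may
merge with or dominate the ventricle, so real-data use requires cropping or
a chamber-separation step that is out of scope here.

## Cycle detection and heart rate

The per-frame area trace is smoothed with a 3-frame centered moving
average; maxima (ED) and minima (ES) are found with a prominence floor of
20% of the smoothed trace range and a minimum spacing of 0.25 s. The
spacing is converted to frames by truncation, not rounding, so that a beat
period sitting exactly on the floor (240 bpm at 30 fps = 7.5 frames) is not
suppressed. Alternation is enforced by dropping the lesser of two
consecutive same-type extrema.

Two boundary conventions matter:

- The record is treated as the half-open window `[0, T)`. A maximum at the
  very first sample (which generic peak finders cannot return) is recovered
  as an ED if the trace falls from it by at least the prominence floor; a
  rising *trailing* edge is discarded, as it marks a cycle completing
  outside the record. Partial cycles at the ends therefore contribute no
  interval statistics.
- **Sub-frame refinement.** Sampled extrema systematically undershoot the
  true peak of the continuous waveform, biasing diastolic measures down and
  systolic measures up, and quantizing beat times to whole frames. Both are
  removed by parabolic-vertex interpolation through each interior extremum
  and its two neighbours: event *times* are refined for heart-rate
  estimation, and each phase *value* (area and both axes) is evaluated at
  the vertex of its own parabola at the area-trace vertex position. On a
  noiseless simulated fish this reduces the worst indicator error from
  ≈ 3% to < 0.3% and heart-rate errors to ≤ 1.5 bpm over 60–240 bpm at
  30 fps. Edge extrema are left unrefined (no left neighbour), which leaves
  a residual positive HR bias below one bpm per 3-s record.

Heart rate is `60 / mean(ED-to-ED interval)`; ED/ES quantities are averaged
over all detected cycles rather than taken from one representative pair,
which matters only for noisy data.

## The simulator

Ground-truth kinematics: full axes contract as
`a(t) = a_ED(1 − c_long·s(t))`, `b(t) = b_ED(1 − c_short·s(t))` with a
raised-cosine pulse `s(t)` of period `1/f` (`s = 0` at ED, `1` at peak
systole). The fraction of the cycle spent contracting is configurable; the
default of 1 (a pure raised cosine) is used because smaller fractions
create a flat diastolic plateau on which the ED extremum is ill-defined for
peak detection, whereas the full-cycle pulse has exactly one well-defined
maximum and minimum per beat.

Rendering: the ellipse is rasterized by pixel-center inclusion at each
frame's midpoint time, blurred by a Gaussian PSF (σ = 1 px default), offset
by the background level, and optionally corrupted by Poisson shot noise and
additive Gaussian read noise, then quantized to 16-bit. Identical
parameters and seed give bit-identical stacks. Every frame carries the
analytic area `πab/4` and axes as ground truth.

Default conditions, chosen as typical for 3-dpf larval imaging: control
HR 150 bpm, diastolic axes 100 × 60 µm, long/short-axis contraction
0.15/0.30, 30 frames/s for 3 s (≥ 5 control cycles, ≥ 3 cycles for the
depressed model group), 0.5 µm/px, foreground 1000 counts over a 100-count
background. The heart-failure model group multiplies beat frequency by 0.6
and both contraction amplitudes by 0.4 — directionally matching a
calcium-channel-blocker insult without asserting its exact magnitudes.
Treatment groups are parameterized by a recovery fraction ρ that linearly
interpolates beat frequency and contraction between the model (ρ = 0) and
control (ρ = 1) values.

Cohorts: per-fish biological variability is lognormal with mean 1 and a
configurable coefficient of variation (default 0.05) applied independently
to beat frequency, both diastolic axes and both contraction amplitudes;
contraction is capped at 0.95 and the short axis at the long axis. Each
fish draws from a stream spawned from the root seed by fish index, so any
fish is reproducible independently of cohort size.

What the simulator does *not* emulate: the atrium and its mechanical
interaction with the ventricle, pericardial background fluorescence, fish
motion and focus drift, photobleaching, arrhythmia, and 3-D effects
(volumes come from a 2-D projection in both simulation and measurement, so
volume-model error against real hearts is not probed). Passing tests
therefore demonstrate that the measurement chain recovers known 2-D
elliptical kinematics through realistic imaging noise — not that the
prolate-spheroid volume or single-chamber segmentation are adequate for any
particular real preparation.

## AHFI scoring

Normalization uses group means (`B = mean_group / mean_control`), not
per-fish normalized values averaged, matching the one-value-per-group
structure of the score. `RCF = (B_t − B_m)/(1 − B_m)` is undefined when the
insult leaves an indicator at the control level; a relative tolerance of
1e-6 on `|1 − B_m|` flags such components, which invalidate the group's
AHFI rather than silently contaminating it. `B_m > 1` (indicator elevated
by the insult) is allowed — the same formula then scores movement back down
toward control — with a warning. Rankings sort by AHFI descending with ties
broken by EF recovery, then label, so reports are deterministic.

Group statistics follow the convention of small-animal phenotyping screens:
mean ± sample SD (n−1), two-tailed two-sample t-tests of each group against
the model group, one-way ANOVA across all groups, and significance flags at
0.05 and 0.01. No multiple-testing correction is applied, and the t-tests
are not post-hoc-protected by the ANOVA; both choices mirror common
practice in this assay class and are easy to tighten downstream.

## Quality control and degenerate inputs

Per fish: ≥ 80% of frames must segment, and ≥ 2 complete ED-to-ED cycles
must be detected (both configurable). Failing fish are excluded, listed
with reasons in the exclusion report, and reduce the group n; they never
abort a run. A missing control or model group aborts with a configuration
error. Flat images, blank stacks and all-invalid phase selections all take
the exclusion path.

## Numerical choices

- Otsu on a zero-dynamic-range frame is undefined → empty mask, invalid
  frame.
- Invalid-frame interpolation is linear in frame index; edges extend the
  nearest valid value.
- Parabolic refinement falls back to the raw sample at trace edges, next to
  invalid frames, or when the three points are collinear; the vertex offset
  is clamped to ±1 frame.
- Negative FS or SV (systolic measure exceeding diastolic) is logged and
  propagated, not rejected: the formulas admit it and masking it would hide
  segmentation problems.
- CSV outputs are written with pandas defaults from deterministic inputs;
  identical seed + configuration reproduce byte-identical files.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
desk scale: single fish for recovery checks, cohorts of 1–2 fish per group
for AHFI identities and the recovery grid, 20 fish per group for the
control-vs-model comparison, and 1000 Monte-Carlo replicates for t-test
calibration. These sizes give comfortable margins on every tolerance while
keeping the full suite under a minute of compute on one core.
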