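# Methods

This note documents the models, conventions and numerical choices
behind each module, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the experimental
literature leaves the procedure open.

## Arena geometry

The arena is modeled as a regular octagon built from its longest
diagonal (40 cm, circumradius 20 cm), giving a side of 15.31 cm — the
nominal side (15 cm) and diagonal are mutually inconsistent for a
regular octagon, and the diagonal was chosen as the defining dimension
because chamber and center areas derive from it. Eight radial dividers
split the periphery into chamber quadrilaterals; the inner octagon
(center region) is sized so each chamber's entry edge is exactly one
entryway wide (5.5 cm), giving an inner circumradius of 7.19 cm. Ports
sit at the midpoints of the outer walls. Chambers are numbered 0–7
counterclockwise from east; all geometry lives in a planar cm frame
with the origin at the arena center, and the camera-pixel frame is an
affine transform owned by the pose readers and generators.

Region classification (`ArenaGeometry.locate`) uses the support
function of the two regular octagons (projections onto the eight wall
normals), which is exact and vectorizes over whole tracks; the shapely
polygons are exposed for plotting and cross-checks only. Boundary
points classify as the more central region; the entry detector's
debounce makes the classifier's boundary convention immaterial.

## Stimulus

Intervals: gamma with shape k = (µ/σ)² and scale θ = σ²/µ, where
µ = 1/rate (s) and σ is the irregularity (ms). This is the unique gamma
parameterization in which rate and irregularity are independent knobs;
σ = 0 is handled as the degenerate periodic limit rather than a gamma
draw. The fixed preset is (10 kHz center, 3 kHz bandwidth, 10 ms
bursts, 70 dB SPL, 4 bursts/s, 31 ms irregularity); the variable regime
draws center frequency (5–15 kHz), rate (3–10 Hz) and irregularity
(1–100 ms) log-uniformly and level (65–90 dB SPL) uniformly in dB.
Log-uniform was chosen because these parameters act multiplicatively
and are conventionally analyzed on log axes; the true sampling law of
the original rig is unknown, so this is a package design choice.

Bursts are white noise band-limited by a 5th-order zero-phase
Butterworth band-pass (≥ 40 dB stopband after forward–backward
filtering), shaped by 1 ms raised-cosine ramps to limit spectral
splatter, and RMS-scaled under the convention that a digital full-scale
sine is 94 dB SPL (configurable). When intervals are shorter than the
burst duration, overlapping bursts are summed with a warning — never
truncated — so the train's interval statistics are preserved.
Calibration is a per-frequency dB correction (target flat level minus
measured level) applied as a linear-phase FIR designed by frequency
sampling; in round-trip tests against a known 2-pole speaker response
the corrected transfer function is flat to well under 1 dB over
5–20 kHz. The error sound is provided as a plain two-tone generator
(8 kHz plus a tritone above) without further claims about the original
synthesis.

## Task simulation

Goals are drawn uniformly with the previous goal excluded (first trial:
uniform over all 8). Policies are stationary:

- *random* visits the 7 eligible ports in a uniformly random order,
  poking each until the goal — the chance benchmark. The goal's rank is
  uniform on {1..7}, so expected ports poked is exactly 4 and
  P(correct) = 1/7; the test suite checks this against brute-force
  enumeration of all orderings.
- *cycling* walks the ring in one direction from a start port
  (fixed or random), poking every port — the post-hearing-loss
  "traplining" pattern. Given a uniform goal its ports-poked
  distribution is also uniform on {1..7}.
- *direct* goes straight to the goal (perfect performance).
- *checker* enters chambers in ring order and pokes only when it
  detects sound there (Bernoulli with probability given by a constant
  or a `detect_prob(level, ear_state)` callable; optional false-alarm
  rate). After a configurable number of silent laps (default 2) it
  falls back to poking every port in ring order, which guarantees
  termination even with detection probability 0 (the bilateral
  hearing-loss regime) and matches the serial-poking behavior seen in
  that regime.

Each visit yields a constant-speed waypoint path center → entryway →
port → entryway → center at 15 cm/s (a synthesis convention — the rig
does not measure locomotion speed), with a 0.5 s dwell at poked ports
and a 1 s inter-trial delay. The simulator logs every event and leaves
exclusion decisions to the scoring module.

## Scoring

`ports_poked` counts **distinct** ports, not raw pokes: with the
previous goal excluded only 7 ports are eligible, and the metric's
stated 1–7 range forces the distinct-port reading (repeated pokes into
the same wrong port count once). Pokes after the first goal poke are
ignored (the trial ends at reward). A session's first trial has no
previous goal, so no exclusion applies; its score is flagged and
excluded from session means by default to preserve the [1, 7] contract.
The learning criterion is strict (mean ports poked < 2.5).
`performance_by_param` is thin glue over Pearson correlation
(scipy.stats) of the log-parameter (linear for dB level) against ports
poked, with log-spaced bin means for plotting.

## Chamber entries

Entry detection runs on the snout keypoint: an entry fires at the first
frame inside a chamber polygon after the snout was in the center
region; the visit ends after 3 consecutive frames (100 ms) back in the
center, and re-crossings sooner merge with the ongoing visit. The
debounce prevents divider-jitter double counting. Missing snout samples
are bridged by linear interpolation up to 5 frames; longer gaps leave
frames unlocated, which hold the previous region state, and an
all-missing snout is an error.

Classification follows the standard taxonomy: duplicates are re-entries
into a chamber already visited in the same trial; cycling entries are
ring-adjacent to the chamber just *exited* (so a trial's first entry is
never cycling); metrics discard duplicates and previous-goal entries
before splitting kept entries into with-poke and without-poke (checks),
so additivity holds per trial. When a poke occurs during a discarded
duplicate visit, the kept first entry of that chamber inherits the
with-poke flag by default ("eventually culminated in a poke"); strict
per-visit attribution is available behind
`attribute_poke_to_first=False`. Trial windows come from the event
log's trial-start and reward times; entries outside any window (e.g.
during the inter-trial delay) are dropped.

Pose I/O supports a SLEAP-analysis-style HDF5 layout (`tracks`
[1 × 2 × nodes × frames], `node_names`, optional affine `transform`)
and a flat CSV dialect (frame, node, x, y).

## Startle

Speed is the per-frame Euclidean displacement of each keypoint averaged
across keypoints, with missing keypoints dropped from that frame's
mean; magnitude is the mean over frames [onset, onset + 5), i.e. the
onset frame is included — 167 ms at 30 fps. 80 and 90 dB stimuli are
pooled. Output stays in px/frame (no chamber calibration is modeled); a
5-frame pre-onset baseline is available for normalization but the raw
magnitude is the primary readout.

## ABR

Cross-talk removal fits a causal 32-tap FIR (2 ms at 16 kHz) by least
squares on the whole recording — an orthogonal projection, so residual
power never exceeds input power — and subtracts the prediction. The
high-pass is a zero-phase 4th-order Butterworth at 100 Hz. Outlier
rejection discards the union of the top 5% of epochs by peak-to-peak
excursion and by SD, with ceiling counts and ties broken toward keeping
earlier epochs; union (rather than sequential application) was chosen
as the more conservative reading. Epochs span −2 to +10 ms around each
click trigger, and left-side averages are inverted so Wave 1 is
expected positive. Wave picking and threshold estimation are out of
scope; the averaged waveform is the terminal output.

## Synthetic data

Generators emulate the structure of the study's recordings, not their
biology:

- **Pose sessions**: simulator waypoints resampled at 30 fps in a
  640 × 480 px camera frame (10 px/cm, centered), snout on the path and
  7 further keypoints (head, trunk, four limbs, tail base) trailing at
  fixed arc-length offsets, plus isotropic Gaussian jitter (default
  2 px). Real tracks additionally contain identity errors, occlusions
  and posture variation that these tracks do not; passing round-trip
  tests therefore demonstrates the detector's geometry and debounce
  logic, not robustness to tracker failure modes.
- **Startle sessions**: reflected Brownian wander (simplest
  tunable-activity baseline) plus, for responsive hearing states, a
  directed displacement burst of configured amplitude for 5 frames at
  each onset; the bilateral profile adds none. Onsets are spaced
  uniformly in 5–30 s.
- **ABR recordings**: a damped-oscillation evoked template (onset 3 ms
  post-click, ~6 ms long, 5 µV peak) at each of 750 triggers (33 ms
  spacing), cross-talk through a known 5-tap FIR, white noise (2 µV
  SD), and 5% planted outlier epochs with 10× noise. The template onset
  is deliberately beyond the 2 ms cross-talk FIR span: on a real rig
  the electrical bleed is instantaneous while the evoked response
  arrives milliseconds later, and keeping that separation means the
  least-squares fit cannot absorb the evoked component. Under these
  defaults the full pipeline recovers the template at r ≈ 0.99 and
  catches every planted outlier.

All generators take a single seed and are bit-reproducible.

## Problem sizes and numerical notes

Validation suites use 2,000-trial simulations for chance-level checks
(binomial SE ≈ 0.008 on fraction correct), 500 pose-track trials for
the entry pipeline (SE ≈ 0.09 on kept entries), ≥ 10⁵ intervals for
stimulus moments (SE < 0.1 ms on the SD), and 1,000 s of burst trains
for the empirical rate — sizes at which the estimators' 3-standard-
error bands separate the derived constants cleanly while keeping the
whole suite fast on a single core. Statistical assertions use 3 SE
bands computed from the sample itself (for the SD, via the sample
fourth moment). Degenerate inputs are rejected with explicit errors
(zero-duration bursts, sub-Nyquist sample rates, constant parameters in
correlation analyses, all-missing snout, fewer than 2 epochs).

## Known limitations

- Agent policies are stationary; learning dynamics are out of scope.
- The pixel↔cm map is a global affine; lens distortion is not modeled.
- The error-sound generator is a nominal two-tone stand-in.
- Startle output is in px/frame; comparisons across rigs with different
  camera geometry require external calibration.
- The ABR module stops at the averaged waveform (no wave latency or
  amplitude scoring).
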