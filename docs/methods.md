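# Methods

This note documents the models, the parameter defaults and why they were
chosen, the numerical choices, and what the simulator does and does not
emulate.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The QA procedure

Dynamic localization QA asks whether an optical surface-monitoring system
reports small, known displacements correctly, in magnitude and in time.  The
procedure drives the treatment couch — with a rigid phantom attached — through
a fixed sequence of single-axis moves and compares what three independent
witnesses saw against what was commanded:

1. the **trajectory log**: the machine's own record of expected and actual
   axis values plus cumulative MU, on a uniform time grid;
2. the **surface log**: the SGRT system's 6-DoF offset of the monitored ROI
   from its reference capture, on the camera's own clock and rate;
3. **MV images** of an implanted ball bearing (bb), one per translation,
   giving a radiographic measurement that does not depend on either log.

Couch coordinates are IEC 61217 (lat = X, lng = Y, vrt = Z, rotations in
degrees normalized to (−180, 180]).  Deviations are signed, measured −
expected; a source passes when every applicable |deviation| is ≤ the SABR
tolerance (1 mm translations, 1° rotations).  The boundary case passes: the
comparison is ≤, which matters for borderline monthly results and is stated
in the report header.

### Motion plan

Defaults: translations {−50, −10, +10, +50} mm on lateral/longitudinal
(gantry 0°) and vertical (gantry 90°); rotations ±3° in 0.5° steps on yaw,
pitch, roll; 50 MU and one MV image per translation.  Design choices where
the procedure leaves freedom:

* **Each step is an absolute offset from the reference pose** — the couch
  returns to zero between axes and sweeps monotonically within an axis
  (−3° → +3°, skipping 0).  This is the simplest deterministic sequencing
  and is recorded in the plan metadata.
* **Rotations are not imaged** (single bb) and deliver no beam.
* **Reference images** (zero-delta steps at gantry 0° and 90°) are modelled
  as image acquisitions without logged MU, so beam-on intervals correspond
  one-to-one with translation steps.  A separate gantry-90° reference is
  required: rows/columns map to different couch axes per gantry angle.
* The 53-step default plan = 48 motion steps + 5 zero-delta home/reference
  steps so the plan starts and ends at the reference pose.

## Synchronization and reduction

* **Interpolation**: per-axis linear, clamped at the ends of the surface
  log's span.  Linear is the conservative choice for a signal that is
  piecewise ramp-and-dwell by construction.
* **Motion onset**: first sample deviating from the baseline (mean of the
  first 1 s) by more than 0.1 mm / 0.1° *and staying beyond threshold for
  0.4 s*.  The threshold sits between the simulated sensor noise
  (σ = 0.05) and the smallest planned motion (0.5° / 10 mm).  The
  persistence window exists because isolated exceedances are not
  independent across samples — they share the noisy baseline estimate — so
  a short window passes occasional runs of noise at 2-σ thresholds; 0.4 s
  (6 surface samples at 15 Hz) suppresses them without biasing the onset
  time, since a real ramp stays above threshold throughout.  Raising the
  threshold can only delay the onset (tested property).
* **Beam segmentation**: a sample is beam-on when the MU increment from the
  previous sample exceeds 1e−3 MU.  The surface log has no beam flag, so
  beam-on always comes from the trajectory log.
* **Dwell segmentation**: rotations deliver no beam, so their per-position
  averages cannot come from MU.  The expected (commanded) series is scanned
  sequentially for each step's stationary interval, trimmed by 0.1 s
  margins to stay clear of ramp edges in interpolated surface data.  For
  beam-delivering steps the beam-on interval (which lies strictly inside
  the dwell) is used instead.
* **Averaging**: plain arithmetic mean over the interval; rotation axes are
  unwrapped first, a no-op at ±3° but wrap-safe in general.
* **Latency**: aligning by motion onset absorbs any true reporting latency —
  the residual lag of an onset-aligned session measures alignment error,
  not hardware.  The quantitative estimate therefore uses normalized
  cross-correlation of the translation traces over ±1 s on a shared-clock
  session, positive = surface lags couch, resolved to the trajectory sample
  period (0.02 s).  Onset alignment itself recovers an injected lag only to
  the *surface* sampling period (~67 ms at 15 Hz), which is why the onset
  route is reported as informational and never pass/fail.

## MV image analysis

* **Detection** = background subtraction (median), matched filter against a
  projected-disc template of the expected diameter (bb ⌀ × SID/SAD), then a
  clipped intensity-weighted centroid over a window just larger than the
  disc (weights below 20 % of the window peak are zeroed so background
  noise cannot pull the centroid).  The NCC map is computed with FFT
  convolutions; the denominator is floored at 1e−6 of its maximum because
  in exactly-constant regions both numerator and denominator cancel to
  rounding noise and the unfloored ratio produces spurious peaks.  A best
  correlation below 0.30 raises a detection-failure: QA must flag a missing
  bb, never guess.  A plain threshold-centroid detector is included as an
  independent cross-check.
* **Magnification**: displacements scale by `pixel_pitch × SAD / SID`
  (0.224 mm/px at the default SAD 1000 / SID 1500 / pitch 0.336 mm
  geometry).  DICOM geometry tags override defaults when present.
* **Axis mapping** (validated end-to-end against the simulator): gantry 0°
  → +col = +lat, +row = +lng; gantry 90° → +col = +vrt, +row = +lng.  The
  beam-axis component is unobservable in a single projection, and rotations
  are never estimated from images.

## The session simulator

The simulator emulates the full experiment so every pipeline stage is
testable without hardware: trapezoidal constant-speed couch ramps
(20 mm/s, 3°/s; gantry 6°/s) between step targets, 2 s dwells, MU ramped
linearly between 0.2 s margins inside each beam dwell, a rigid-phantom
surface response (surface offset ≡ couch offset, optionally scaled per axis
for negative-control tests) delayed by a configurable latency, sampled at
15 Hz with i.i.d. Gaussian noise (σ = 0.05 mm / 0.05°), and MV images of
the projected bb with an erf (Gaussian-PSF-blurred) edge profile.  The erf
profile is radially symmetric and effectively band-limited, so the sampled
image's intensity-weighted centroid coincides with the projected center to
well below 0.01 px — a hard-edged disc aliases at the ~0.01 px level, which
would dominate the zero-noise closure budget.  One seeded generator drives
all draws; identical (seed, plan, config) give bit-identical sessions.

Surface rates and noise spectra of real camera systems are not published;
the defaults are placeholders of clinically plausible magnitude.  The
simulator does **not** model: couch servo error (expected ≡ actual; real
machines show ~0.1 mm discrepancies), deformable or partially occluded
surfaces, camera-pod optics and calibration drift, MV scatter/beam physics,
or image distortion.  Passing tests therefore demonstrate that the
*analysis* is exact and statistically calibrated under the stated forward
model — not that any particular hardware meets tolerance.

### Statistical calibration

Averaging interpolated surface samples makes each position mean a weighted
sum of the raw noise draws, so its exact standard error is σ·√(Σw²) with
weights given by the interpolation (equivalently an effective sample count
1/Σw², smaller than the grid-sample count).  `interval_mean_weights`
computes that map; the suite verifies over 200 seeded sessions that
standardized per-position errors are N(0, 1) (KS test, α = 0.01) and that a
0.20 s injected latency is recovered by cross-correlation within one
trajectory sample in ≥95 % of sessions.

## Problem sizes and tolerances used in the checks

Default sessions are ~175 s at 50 Hz (~8700 trajectory samples, 14 images
at 512²); the noise-calibration study uses 200 sessions without images; the
detection study uses 500 noisy 96² images (SNR 10, sub-pixel centers) plus
100 bb-free images.  Zero-noise closure is asserted at 1e−3 mm/°
(measured ~8e−4 mm, dominated by residual centroid discretization);
averaging matches brute force at 1e−12; log round-trips are exact at the
dialect's six-decimal precision; plan XML round-trips byte-identically
(floats serialized in shortest-repr form).

## Known limitations

* Onset-based alignment cannot measure latency (by construction); the
  cross-correlation estimate requires logs that share a clock, which the
  simulator provides but older clinical systems may not.
* The trajectory dialect is an open CSV stand-in; converting vendor binary
  trajectory logs is out of scope.
* Rotation verification relies entirely on the two log sources; radiographic
  rotation checks would need a multi-bb or wire phantom.
* `segment_dwells` assumes the expected series reaches each step's target
  exactly and in plan order; grossly truncated deliveries raise a
  synchronization error rather than producing partial summaries.
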