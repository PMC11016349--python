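# sgrt-dynqa

Automated monthly QA of **dynamic localization accuracy** for surface-guided
radiotherapy (SGRT) systems.

SGRT systems monitor a patient's surface in real time and must report small
displacements accurately (in magnitude and in time) to be trusted for
intra-fraction motion monitoring during stereotactic treatments.  AAPM TG-302
recommends a monthly dynamic localization test, but no vendor supplies one.
This package implements an automated procedure: a scripted couch/gantry motion
sequence moves a rigid phantom (with one implanted radio-opaque ball bearing,
"bb") through known translations and rotations while three independent data
streams record what happened — the linac's trajectory log, the SGRT surface
log, and MV portal images of the bb.  The analysis aligns the streams,
averages each at every couch position, measures the bb displacement in each
image, and reports deviations from the commanded motions against the AAPM
TG-142 stereotactic (SABR) tolerances of **1 mm and 1°**.

For medical physicists: the library is the analysis engine; the `sgrt-dynqa`
CLI builds plans, analyzes sessions, and — because no linac is needed to test
the pipeline — simulates complete sessions with known ground truth.

## Method in brief

* **Motion plan** — couch translations of ±10 and ±50 mm on the lateral and
  longitudinal axes at gantry 0° and on the vertical axis at gantry 90°, each
  followed by an MV image and 50 MU; then yaw/pitch/roll sweeps of ±3° in
  0.5° increments (rotations are not imaged: one bb cannot constrain them).
  Rendered as a versioned XML control script.
* **Synchronization** — the surface log is linearly interpolated onto the
  trajectory log's uniform grid and aligned by the first instance of motion
  in each stream (threshold 0.1 mm/0.1° above a 1 s baseline, sustained for
  0.4 s).  Couch and surface poses are averaged over beam-on time (or the
  stationary dwell, for rotations) at each position.
* **MV analysis** — the bb center is found by matched filtering against a
  projected-disc template plus an intensity-weighted sub-pixel centroid;
  pixel displacements from the reference image scale to isocenter
  millimetres by `pitch × SAD / SID` (0.336 × 1000/1500 = 0.224 mm/px at the
  default geometry).
* **Report** — signed deviations (measured − expected) per step, axis and
  source; a source passes iff every |deviation| ≤ tolerance (boundary
  passes).
* **Latency** — onset-based alignment absorbs true latency (the lag left
  afterwards is alignment error), so the quantitative latency estimate uses
  normalized cross-correlation on shared-clock sessions and is reported as
  informational.

## Worked example

```sh
sgrt-dynqa plan --out plan.xml
sgrt-dynqa simulate --plan plan.xml --seed 3 --out session/
sgrt-dynqa analyze --plan plan.xml --traj session/trajlog.csv \
    --surf session/surflog.csv --images session/images --out report/
```

prints (simulator defaults: 0.05 mm/0.05° surface noise, no latency):

```
{
 "verdicts": {
  "traj": true,
  "surf": true,
  "mv": true
 },
 "max_dev": {
  "traj": {
   "translation": 0.0,
   "rotation": 0.0
  },
  "surf": {
   "translation": -0.018369842464446506,
   "rotation": -0.025859837405619146
  },
  "mv": {
   "translation": -0.0007860890756887784,
   "rotation": null
  }
 }
}
```

Read: the machine reported its own motions exactly (trajectory deviations 0);
the simulated surface system's worst error was −0.018 mm / −0.026°, dominated
by sensor noise averaged over each dwell; MV imaging recovered the
translations to −0.0008 mm; every source is within the 1 mm / 1° SABR
tolerances, so the monthly check passes.  `report/report.md` holds the
per-step table and `report/report.json` the machine-readable record.

The same session can be driven from Python:

```python
from sgrt_dynqa import (SimulationConfig, analyze_session, build_motion_plan,
                        simulate_session)

plan = build_motion_plan()
traj, surf, images, truth = simulate_session(plan, SimulationConfig(seed=3))
qa = analyze_session(plan, traj, surf, images)
print(qa.verdicts, qa.max_dev["mv"]["translation"])
```

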