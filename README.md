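# tiltscope

Analysis tools for ratiometric Ca²⁺ imaging on a **tiltable-objective
microscope** — a design in which the objective and specimen rotate on a
motorized stage while the camera stays put, so a larval-zebrafish
vestibular organ can be imaged during real static tilt (gravity
re-orientation, up to 360°) and vibration (2° trapezoidal cycles at
2.2 Hz). The package is aimed at people analyzing such recordings, and at
anyone who wants a fully ground-truthed synthetic benchmark for rotating
two-channel fluorescence data.

Because the camera does not rotate, the images spin about a fixed center,
and the rotating optical train imposes position-dependent gain swings that
can exceed 50% of a channel's intensity. Both problems are handled the way
the instrument's analysis requires:

* **registration** — per-frame rotation angles and the rotation center are
  estimated from fluorescent-bead recordings by least-squares rigid fits
  of tracked bead constellations, frames are counter-rotated, and residual
  drift is corrected by log-polar + phase-correlation refinement at the
  1/10-pixel level;
* **ratiometric ΔR/R0** — activity is the fractional change of the
  green/red ratio from its pre-stimulus baseline,
  ΔR/R0 = R(t)/R0 − 1, which cancels the (almost entirely common-mode)
  multiplicative artifact;
* **tuning maps** — per-cell response vectors are the vector sum of the
  pitch- and roll-session amplitudes, v = (A_pitch, A_roll) on the
  rostro-caudal/medio-lateral axes with length ‖v‖ = √(A_p² + A_r²),
  pooled across samples on a grid whose spacing is the mean
  nearest-neighbor cell distance;
* **compartment statistics** — striolar vs extrastriolar mean vector
  lengths, paired within 10° hair-bundle-polarity bins per utricle, are
  compared with a two-sided Wilcoxon signed-rank test (exact enumeration
  for n ≤ 15);
* **photoconversion profiling** — red/green Kaede ratio gradients in 3-D
  confocal volumes, smoothed, thresholded, and binned along anatomical
  axes.

A first-class synthetic-data module generates all of this with known
ground truth: macula layouts with a hair-bundle polarity field that
reverses at the line of polarity reversal, a striola band that prefers
vibration, a phenomenological transduction/indicator response model, and
rendered rotating stacks with the instrument's artifact structure (smooth
common-mode gain fields, hot pixels, bleaching, photon noise, W-view
export).

## Worked example

Simulate the vibration stimulus, compute the inertial acceleration it
imposes on a specimen 0.1 m off the rotation axis, and find the stimulus
fundamental:

```python
from tiltscope import (make_vibration_trajectory, inertial_acceleration,
                       acceleration_spectrum)

traj = make_vibration_trajectory()          # 2° cycles at 2.2 Hz, 18 s
acc = inertial_acceleration(traj, 0.1)      # tangential r·α, m/s²
spec = acceleration_spectrum(acc.tangential, traj.sample_rate)
print(f"peak tangential acceleration: {abs(acc.tangential).max():.2f} m/s^2")
print(f"stimulus fundamental: {spec.lowest_peak():.1f} Hz")
```

```
peak tangential acceleration: 1.75 m/s^2
stimulus fundamental: 2.2 Hz
```

Render a rotating bead stack with the default artifact model, register
it, and verify that ratiometric measurement suppresses the single-channel
artifact:

```python
import numpy as np
from tiltscope import make_tilt_trajectory
from tiltscope.synthetic import Acquisition, make_bead_field, bead_sources, render_stack
from tiltscope.pipeline import register_stack, measure_stack

traj = make_tilt_trajectory("tilt360")            # 360° tilt protocol
acq = Acquisition(fov=(256, 256))
beads = make_bead_field(35, fov=acq.fov, seed=1)
stack = render_stack(bead_sources(beads), traj, acq=acq, seed=1)

reg, est = register_stack(stack)                  # hot pixels, rotation, drift
traces = measure_stack(reg, beads.offsets_px + acq.center(), 1.5, traj)

base = traces.green[:, traces.t < traj.first_motion_time()].mean(axis=1)
dff = traces.green / base[:, None] - 1.0
print(f"max single-channel |dF/F0|: {100 * abs(dff).max():.0f} %")
print(f"max ratiometric |dR/R0|:    {100 * abs(traces.drr).max():.1f} %")
```

```
max single-channel |dF/F0|: 60 %
max ratiometric |dR/R0|:    5.2 %
```

The beads swing by more than half their brightness as they sweep through
the static gain field, yet the green/red ratio confines the residual to a
few percent — the margin that makes 10%/5% activation thresholds usable
for real responses.

A full synthetic experiment (render → register → ΔR/R0 → classify →
vector maps → striola statistics) with one imaged utricle and two
trace-level utricles:

```sh
tiltscope demo --seed 5 --out demo_run
```

which prints a JSON summary (cell counts, activated fractions, the
striolar-vs-extrastriolar p-values) and writes `cells.csv`,
`grid_tilt.csv`, `striola_pairs.csv`, `striola_tests.csv` and
`report.png` into `demo_run/`.

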