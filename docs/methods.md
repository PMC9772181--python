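# Methods

## The measurement problem

A tiltable-objective microscope rotates the objective and specimen
together on a motorized stage while a stationary camera records two-color
fluorescence. This lets one image vestibular organs (the utricular macula
and the vestibular ganglion, VG) of larval zebrafish during physiological
stimuli: slow large-angle rotation applies static tilt (gravity
re-orientation), and fast small-angle bidirectional rotation applies
vibration (inertial acceleration). Two consequences dominate the data:

1. the scene rotates in the image about a fixed center, and
2. the excitation/collection efficiency at a given camera position changes
   as the optical train rotates, producing single-channel intensity swings
   that can exceed 50% and would swamp any calcium signal.

The artifact is almost entirely multiplicative and common to the green
(activity indicator) and red (activity-independent) channels, so the
green/red ratio R cancels it; activity is quantified as ΔR/R0, the
fractional change of R from its pre-stimulus baseline R0.

`tiltscope` implements the stimulus kinematics, a ground-truthed generator
of such recordings, the registration and ratiometric chain, response
classification and vector mapping, the striola/extrastriola paired
statistics, and photoconversion gradient profiling. Everything runs on
synthetic data whose ground truth is known, so every stage is testable
against the quantity it is supposed to recover.

## Stage kinematics (`tiltscope.stimulus`)

Three protocols, assembled from analytic trapezoidal (or triangular)
velocity segments on a uniform grid (default 1 kHz, matching accelerometer
digitization; camera-rate series are obtained by decimation):

* **tilt90** — still 5 s, +90°, hold 5 s, return, hold 5 s, −90°, hold
  5 s, return, hold 5 s; v_max = 25°/s, |α| = 24.9°/s².
* **tilt360** — still 3 s, +360°, hold 6 s, −360°, hold 3 s;
  v_max = 15°/s, |α| = 24.9°/s².
* **vibration** — 2° peak-to-peak trapezoidal position cycles at 2.2 Hz
  for 18 s; v_max = 1000°/s, |α| = 1000°/s². The 18 s / 2.2 Hz product is
  rounded to 40 whole cycles (18.18 s of motion).

θ, ω and α are evaluated in closed form per segment, so the discrete
series is exact to machine precision; a configurable exponentially
decaying ring (default 0.02°, 80 Hz, τ = 50 ms on tilt protocols) can be
injected at each motion stop to emulate the mechanical ringing of a real
stage and spread the stimulus spectrum into the tens-of-Hz band. The ring
perturbs θ only; the stored ω/α profiles remain the nominal trapezoids,
and kinematic-limit checks refer to those.

Gravity decomposes as X(centripetal) = g·cosθ, Y(tangential) = g·sinθ
with g = 9.806 m/s². Inertial acceleration of a specimen at radius r from
the axis is tangential r·θ̈ and centripetal r·θ̇², computed by central
differences of the realised θ (one-sided at the ends). The radial offset
is not a measured quantity here; it defaults to 0.1 m and all inertial
magnitudes scale linearly with it. Spectra are one-sided rectangular-
window DFT amplitudes, zero-padded to the next power of two so bin
positions are stable; peak finding enforces a 1 Hz minimum separation so
sinc sidelobes of the rectangular window are not reported as peaks.
Positive θ means nose-down (pitch sessions) or lateral-down (roll
sessions) throughout.

## The synthetic recordings (`tiltscope.synthetic`)

**Macula layout.** Cells are dart-thrown into an ellipse (default
semi-axes 55 × 30 µm, 85 cells, ≥5 µm separation, giving a mean
nearest-neighbor distance near 5–6 µm, the scale used for grid pooling).
The hair-bundle polarity field fans out from a virtual focus placed
1.6 semi-minor-axes medial of the center; the line of polarity reversal
(LPR) is the locus at 95% of the maximal focus distance, which runs along
the lateral edge and around the poles. Cells beyond the LPR have their
polarity negated (the medial-down-preferring population), and the striola
is the band beyond 84% of that distance — so every reversed cell is
striolar, matching the observation that medial-down preference exists
only inside the striola. With these defaults roughly a third of cells are
striolar and ~13% are reversed.

**Response model.** A phenomenological transduction + indicator model.
For a session along axis â (rostral for pitch, lateral for roll) the
in-plane gravity drive is sinθ·â and each cell's tilt drive is

    gain · relu(p·a) − negative_lobe_ratio · gain · relu(−p·a)

with the negative term only for biphasic cells (a seeded Bernoulli draw,
default fraction 0.5, lobe ratio 0.15). Tilt gains are 0.80 ΔR/R0 per g
extrastriolar and 0.25 striolar. The vibration drive is a leaky
accumulator (τ = 4 s) of |p·â| · |a_tangential|/g with gains 0.90 (g·s)⁻¹
striolar and 0.08 extrastriolar — so at the default stimulus (~0.07 g mean
rectified tangential acceleration) striolar cells plateau near 25% ΔR/R0
and extrastriolar cells stay under the 5% activation threshold. This
encodes, as generative structure, the finding the analysis is meant to
detect: the striola prefers vibration, the extrastriola static tilt; the
statistics module then has real power to detect it from measured data.
Drives pass through first-order indicator kinetics (rise 0.25 s, decay
1 s); a VGN preset adds an adaptation stage (τ = 3 s, 40% persistent)
whose responses decay during holds. Both pathways are always active, so
tilt ramps impose a (small, realistic) inertial contribution. The gains
were fixed once, from the magnitudes such instruments report for these
cell classes (tilt responses of order 100% ΔR/R0, vibration responses of
order tens of percent), before any end-to-end testing and have not been
revisited.

**Rendering.** Sources are isotropic integrated Gaussians (σ = 0.4 ×
soma radius; beads σ = 1.5 px) placed at positions rotated by the frame's
stage angle about a rotation center slightly off the image center (so the
center is a genuinely estimated quantity). Camera geometry follows the
instrument: 3.4 px/µm, 10 frames/s, 448 × 456 px per channel by default;
rows increase caudally and columns laterally for a left-side specimen,
right-side specimens are mirrored in columns, and roll sessions yaw the
anatomy 90° in the camera. The artifact model multiplies each channel by
a static smooth gain field (sum of 3–5 seeded Gaussian bumps, peak
excursion ±0.5) composed of a shared field plus (1 − common-mode
fraction) of a channel-specific field. The common-mode fraction defaults
to 0.98 — how common-mode the real artifact is has not been quantified,
and this value reproduces the artifact envelopes the instrument exhibits
(±10% residual ΔR/R0 during 360° tilt, ±5% during vibration, >50%
single-channel swings) under the other defaults. Per-frame channel gain noise (SD 1%), linear bleach
trends, a flat background (100 counts), Poisson photon noise and
constant-value hot pixels (3 per sensor by default) complete the model.
Raw export stacks green above red in a single 16-bit image ("W-view").

**Photoconversion volumes.** An ellipsoidal "utricle" mask contains a
fibrous compartment (smoothed-noise threshold at a requested fill
fraction) with bright green signal; red = green × ratio, with the ratio
ramping linearly along a chosen axis between configurable endpoints and
the ground-truth profile returned alongside.

## Registration (`tiltscope.registration`)

* **Channel split** of W-view frames, undoing the manual red-vs-green
  sensor alignment offsets.
* **Hot pixels**: flagged automatically as pixels with near-zero temporal
  variance and intensity above the 99.9th percentile of the median frame,
  then replaced per frame by the median of their unflagged 3 × 3
  neighbors. (The real instrument knew its hot pixels; the variance rule
  is this package's auto-detection and is degenerate on noise-free static
  scenes, where any constant bright pixel looks "hot".)
* **Rotation estimation** from bead recordings: per frame, sources are
  detected (adaptive threshold, intensity-weighted centroids; elongated
  or multi-peaked components are flagged as merged and excluded), matched
  to the reference constellation by mutual nearest neighbors after
  predicting positions with an extrapolated rotation, and fit by
  least-squares rigid rotation. The rotation center is solved from the
  rigid fits of frames rotated > 2° and fixed; angles are then re-fit
  about it and unwrapped online against the predicted branch. Angle
  errors on default synthetic beads are ~0.01° (max), and the bead-derived
  sequence is reused for fish stacks recorded with the same stimulus, as
  at the instrument. A fixed center must be supplied when only one bead
  is trackable; symmetric two-bead constellations centered on the
  rotation axis are flagged as 180°-ambiguous.
* **Derotation**: bilinear counter-rotation about the estimated center;
  out-of-field pixels are filled with the frame background and excluded
  from a propagated valid-pixel mask (with a 1-px bilinear guard band).
* **Refinement**: pass 1 estimates residual rotation by phase correlation
  of log-polar FFT magnitudes (applied only between 0.02° and 1°, iterated
  up to three times; accuracy is coarse, a few tenths of a degree, which
  suffices for its role of catching drift the derotation missed); pass 2
  estimates translation by phase correlation with 1/100-px Fourier
  upsampling against the temporal median of the first pre-stimulus
  second. Frames whose correlation peak is weak inherit the previous
  transform and are flagged. All FFT work runs on a centered
  power-of-two crop for speed.
* **Background**: the first-percentile intensity of a non-fluorescent
  region (auto: lowest decile of the temporal mean) subtracted per
  channel, clipped at zero.
* **Cross-sample alignment**: right-ear maps are mirrored about the
  rostro-caudal axis (all *_ml columns negated) and every map is
  translated so its lateral-edge landmark sits at the common origin.

The residual-transform family is a similarity/translation pair — a
documented package choice; nothing in the processing requires a richer
family once the rotation itself comes from the bead fit.

## Ratiometric quantification (`tiltscope.ratiometric`)

Pixelwise: per-frame 3 × 3 median filter per channel, pixel ratio, R0 =
mean ratio over the pre-motion baseline window, ΔR/R0 = R/R0 − 1. Pixels
with red below 5% of the red median are masked instead of producing
unstable ratios; masked pixels never propagate NaNs into means. ROI-wise:
channel means over disc ROIs (beads: 1.5 µm radius) or arbitrary masks,
ratio, R0 from pre-motion frames, and a centered 3-frame boxcar (edges
truncated) applied to the ratio — equivalent to smoothing ΔR/R0, and only
ROI traces are smoothed, not pixel maps. Bleaching/photoconversion trends
are removed per channel by fitting lines to the quiet windows before the
first and after the last stage motion and interpolating linearly between
the fitted endpoint values; the trend minus its initial value is
subtracted before the ratio is formed.

## Response quantification (`tiltscope.responses`)

Amplitude windows: hair-cell tilt = mean ΔR/R0 over the full ±90° hold
plateau; VGN tilt = mean over the closed ±2 s window around the instant
θ first reaches each extreme (41 frames at 10 /s, inclusive reading);
vibration = mean over the last 4.5 s of stimulus-on time. Activation
thresholds are strict: > 10% for tilt, > 5% for vibration (boundary
equality does not activate). Hair-cell preference is the direction of the
larger activating amplitude, with "biphasic" assigned when the
anti-preferred amplitude falls below −5% — half the tilt activation
threshold, a package convention chosen because negative lobes are several
times smaller than the positive responses. VGN preference uses the twofold rule (amplitude more than 2×
the opposite direction, opposite clipped at zero). Response vectors map
nose-down→+rostral and lateral-down→+lateral, length = √(pitch² + roll²);
vibration responses stay axis-aligned bars with a root-sum-square
combined length. Grid summaries use a square grid whose spacing is the
mean within-sample nearest-neighbor distance; each cell joins its nearest
grid point (ties to the lowest index) and vectors are averaged
componentwise per point.

## Striola statistics (`tiltscope.striola`)

Polarity groups are 10° bins of the preferred-vector angle (bin edges at
multiples of 10° from 0° = rostral — the binning origin is a convention),
per utricle. Pairing is per (utricle × bin); groups without extrastriolar
members (the reversed, medial-down groups) are excluded. The two-sided
Wilcoxon signed-rank test drops zero differences, mid-ranks ties,
enumerates the exact null over all 2ⁿ sign assignments for n ≤ 15 (valid
under ties), and uses the tie-corrected normal approximation without
continuity correction above; it is cross-checked against an independent
enumeration oracle and against `scipy.stats.wilcoxon` in the tests.

## Photoconversion profiling (`tiltscope.photoconversion`)

Per-channel 3-D Gaussian smoothing with σ = 1 voxel truncated to a
5 × 5 × 5 support (the window size is the field's convention; the σ
within it is a package choice), Otsu thresholding of the in-ROI green channel
(override allowed) with optional exclusion masks, and red/green ratio
profiles binned along an axis normalized to the retained voxel extent
(normalized-extent bins are the default because the source does not state
absolute-µm binning), reported as mean ± SEM per bin with empty bins
omitted.

## Pipeline scale and runtime

`run_pipeline` renders and fully processes `n_rendered` utricles
(bead reference stack per session, registration, disc-ROI measurement)
and evaluates the remaining utricles at trace level — the same response
model measured with the same amplitude windows, skipping only the imaging
round trip — before pooling maps, grids and the paired statistics. One
rendered utricle at full scale (85 cells, 448 × 456 px, four stacks plus
bead references) takes a few minutes on one CPU; `demo_config()` uses a
reduced organ (40 cells, 30 × 18 µm, 256 px field, 3 utricles) and
completes in about two minutes. Test and acceptance runs use 256-px bead
fields with 35 beads per seed for the artifact-suppression numbers;
these sizes are package choices that leave the artifact model and
protocols at their defaults. Outputs are CSV tables (cells,
grid vectors, paired groups, test summaries) plus the resolved config;
reruns with the same config and seed are byte-identical. A single seed
fans out per stage through `SeedSequence(seed, crc32(stage))`, so stages
can be rerun in isolation.

## What the synthetic data does and does not show

The generator reproduces the geometry (rotating scene, off-center axis),
the artifact structure (common-mode gain field, hot pixels, bleaching,
photon noise) and the biological organization (polarity fan with LPR
reversal, striola band, compartment-specific gains) of the real
recordings, with severities matching the artifact envelopes quoted
above.
Passing tests therefore show that the chain recovers known ground truth
under those conditions. They do not validate against real optics
(aberrations, defocus during tilt, non-rigid tissue motion), real
indicator nonlinearity or saturation, otolith mechanics, or the actual
deposited recordings, none of which are modeled.

## Known limitations

* The log-polar similarity pass resolves residual rotation only to a few
  tenths of a degree on sparse scenes; the primary rotation estimate must
  come from the bead fit.
* Hot-pixel auto-detection assumes temporal noise everywhere except hot
  pixels; on synthetic noise-free static stacks it would flag any bright
  static pixel.
* ROI measurements of closely packed somata (< ~2 spot σ apart) have
  percent-level crosstalk from neighboring cells' green modulation —
  present in real data too, and not corrected.
* The Wilcoxon normal approximation is used above n = 15; the paired
  comparisons at typical pooled scale (n ≈ 18 groups) fall in this
  regime, where exact and approximate p-values differ negligibly.
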