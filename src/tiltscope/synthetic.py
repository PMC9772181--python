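"""Ground-truthed synthetic data: bead fields, macula layouts, response
time courses, rendered rotating two-channel stacks, and photoconversion
volumes.

The generator emulates what the tiltable-objective microscope records:

* the camera does not rotate with the stage, so the scene rotates in the
  image about a fixed rotation center;
* a static, spatially non-uniform excitation/collection gain field in the
  camera frame makes single-channel intensities swing by more than 50% as
  sources move through it during large tilts; the swing is almost entirely
  common to the green and red channels, which is what ratiometric ΔR/R0
  cancels;
* hair cells carry a hair-bundle polarity field that reverses across a
  line of polarity reversal (LPR) near the lateral edge; a striolar band
  adjacent to the LPR responds preferentially to vibration while the
  extrastriola prefers static tilt;
* hot pixels, linear bleaching/photoconversion trends, background counts
  and photon noise complete the artifact model.

All randomness flows through a single integer seed per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .stimulus import G0, StageTrajectory, inertial_acceleration

__all__ = [
    "BeadField",
    "MaculaLayout",
    "ResponseModel",
    "ArtifactModel",
    "Acquisition",
    "TwoChannelStack",
    "TruthTraces",
    "make_bead_field",
    "make_macula_layout",
    "simulate_responses",
    "render_stack",
    "make_photoconversion_volume",
    "bead_sources",
    "layout_sources",
    "hair_cell_model",
    "vgn_model",
]

SESSION_AXES = {"pitch": np.array([1.0, 0.0]),  # rostro-caudal, +=rostral
                "roll": np.array([0.0, 1.0])}   # medio-lateral, +=lateral


# ---------------------------------------------------------------------------
# point-source fields


@dataclass
class BeadField:
    """Point sources in the rotating specimen frame.

    ``offsets_px`` are (row, col) offsets from the rotation center at zero
    stage angle; green/red are total fluxes in camera counts per frame.
    """

    offsets_px: np.ndarray
    green: np.ndarray
    red: np.ndarray
    sigma_px: float
    fov: tuple
    pixel_size_um: float
    seed: int

    @property
    def n(self) -> int:
        return len(self.offsets_px)


def _dart_throw(rng, n, radius, min_sep, max_tries=20000):
    pts = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} points with separation {min_sep:.1f} px "
                f"inside radius {radius:.1f} px"
            )
        r = radius * np.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * np.pi)
        p = np.array([r * np.sin(a), r * np.cos(a)])
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
    return np.array(pts)


def make_bead_field(
    n_beads: int = 40,
    fov: tuple = (448, 456),
    seed: int = 0,
    *,
    min_separation_um: float = 3.0,
    pixel_size_um: float = 1.0 / 3.4,
    margin_px: float = 14.0,
    sigma_px: float = 1.5,
    flux: float = 22000.0,
) -> BeadField:
    """Seeded field of solitary fluorescent beads.

    Beads are confined to the circle inscribed in the FOV (minus a margin)
    so they remain imaged throughout a full 360° rotation, and separated by
    at least ``min_separation_um`` so they stay solitary.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    radius = min(fov) / 2.0 - margin_px
    min_sep = min_separation_um / pixel_size_um
    if radius <= min_sep:
        raise ValueError("FOV too small for the requested separation")
    offsets = _dart_throw(rng, n_beads, radius, min_sep)
    green = flux * rng.lognormal(0.0, 0.25, n_beads)
    red = flux * rng.lognormal(0.0, 0.25, n_beads)
    return BeadField(offsets_px=offsets, green=green, red=red,
                     sigma_px=sigma_px, fov=tuple(fov),
                     pixel_size_um=pixel_size_um, seed=seed)


# ---------------------------------------------------------------------------
# macula layout


@dataclass
class MaculaLayout:
    """Hair-cell positions, polarity field and striola membership.

    ``cells`` columns: cell_id, x_rc, y_ml (µm; +rostral / +lateral),
    pol_rc, pol_ml (unit polarity vector), striolar (bool), soma_radius_um.
    The polarity field fans out from a virtual focus medial of the organ and
    reverses sign for cells beyond the LPR (a curve at fixed distance from
    that focus, running along the lateral edge and around the poles).
    """

    cells: pd.DataFrame
    side: str
    semi_axes_um: tuple
    focus_um: tuple
    lpr_distance_um: float
    striola_inner_um: float
    seed: int

    @property
    def n(self) -> int:
        return len(self.cells)

    def polarity_angle_deg(self) -> np.ndarray:
        """Polarity direction, degrees CCW from rostral in the (rc, ml) plane."""
        return np.degrees(
            np.arctan2(self.cells.pol_ml, self.cells.pol_rc)
        ) % 360.0


def make_macula_layout(
    n_cells: int = 85,
    seed: int = 0,
    side: str = "left",
    *,
    semi_axes_um: tuple = (55.0, 30.0),
    min_sep_um: float = 5.0,
    soma_radius_um: float = 3.5,
    lpr_frac: float = 0.95,
    striola_frac: float = 0.84,
) -> MaculaLayout:
    """Seeded utricular macula with a reversing polarity field.

    Cell density is tuned so ~85 cells give a mean nearest-neighbor distance
    near 5 µm.  ``lpr_frac``/``striola_frac`` position the LPR and the inner
    striola border as fractions of the maximum focus distance, which puts
    every reversed (medial-down preferring) cell inside the striola band.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    rng = np.random.default_rng(seed)
    a, b = semi_axes_um
    pts = []
    tries = 0
    while len(pts) < n_cells:
        tries += 1
        if tries > 100000:
            raise ValueError("could not place cells; lower n_cells or min_sep_um")
        p = np.array([rng.uniform(-a, a), rng.uniform(-b, b)])
        if (p[0] / a) ** 2 + (p[1] / b) ** 2 > 1.0:
            continue
        if all(np.hypot(*(p - q)) >= min_sep_um for q in pts):
            pts.append(p)
    pts = np.array(pts)

    focus = np.array([0.0, -1.6 * b])
    d_max = 1.6 * b + b  # focus distance at the lateral edge
    d_lpr = lpr_frac * d_max
    d_str = striola_frac * d_max
    rel = pts - focus
    dist = np.hypot(rel[:, 0], rel[:, 1])
    pol = rel / dist[:, None]
    reversed_mask = dist > d_lpr
    pol[reversed_mask] *= -1.0
    striolar = dist >= d_str

    cells = pd.DataFrame({
        "cell_id": np.arange(len(pts)),
        "x_rc": pts[:, 0],
        "y_ml": pts[:, 1],
        "pol_rc": pol[:, 0],
        "pol_ml": pol[:, 1],
        "striolar": striolar,
        "soma_radius_um": np.full(len(pts), soma_radius_um),
    })
    return MaculaLayout(cells=cells, side=side, semi_axes_um=tuple(semi_axes_um),
                        focus_um=tuple(focus), lpr_distance_um=d_lpr,
                        striola_inner_um=d_str, seed=seed)


# ---------------------------------------------------------------------------
# response model


@dataclass
class ResponseModel:
    """Phenomenological transduction + indicator model.

    Tilt drive per cell: gain × relu(p·a(t)) − negative_lobe_ratio × gain ×
    relu(−p·a(t)) for biphasic cells, where a(t) is the in-plane gravity
    component along the session axis (g-units) and p the polarity vector.
    Vibration drive: leaky accumulation (time constant ``vibration_tau``) of
    |p·axis|·|a_tangential(t)| in g, scaled by the compartment vibration
    gain.  Both pass through first-order indicator kinetics with separate
    rise/decay time constants; an optional adaptation stage (VGNs) lets the
    response decay toward ``adapt_persist`` × drive during sustained holds.

    Gains are fractional ΔR/R0 per g (tilt) and per g·s (vibration).
    """

    tilt_gain_extrastriola: float = 0.80
    tilt_gain_striola: float = 0.25
    vibration_gain_striola: float = 0.90
    vibration_gain_extrastriola: float = 0.08
    vibration_tau: float = 4.0
    biphasic_fraction: float = 0.5
    negative_lobe_ratio: float = 0.15
    indicator_rise_tau: float = 0.25
    indicator_decay_tau: float = 1.0
    adapt_tau: float | None = None
    adapt_persist: float = 0.4

    def __post_init__(self) -> None:
        if min(self.tilt_gain_extrastriola, self.tilt_gain_striola,
               self.vibration_gain_striola, self.vibration_gain_extrastriola) < 0:
            raise ValueError("gains must be nonnegative")
        if self.indicator_rise_tau <= 0 or self.indicator_decay_tau <= 0:
            raise ValueError("indicator time constants must be positive")
        if not self.tilt_gain_striola < self.tilt_gain_extrastriola:
            raise ValueError("striolar tilt gain must be below extrastriolar")
        if not self.vibration_gain_striola > self.vibration_gain_extrastriola:
            raise ValueError("striolar vibration gain must exceed extrastriolar")
        if not 0 <= self.biphasic_fraction <= 1:
            raise ValueError("biphasic_fraction must be in [0, 1]")


def hair_cell_model(**overrides) -> ResponseModel:
    return ResponseModel(**overrides)


def vgn_model(**overrides) -> ResponseModel:
    """VGN preset: same gains but adapting responses that decay during holds."""
    kw = dict(adapt_tau=3.0, adapt_persist=0.4, biphasic_fraction=0.0)
    kw.update(overrides)
    return ResponseModel(**kw)


@dataclass
class TruthTraces:
    """Noise-free fractional green-fluorescence change per cell."""

    t: np.ndarray            # camera frame times, s
    traces: np.ndarray       # (n_cells, T) fractional change
    biphasic: np.ndarray     # (n_cells,) bool
    session: str
    protocol: str


def simulate_responses(
    layout: MaculaLayout,
    traj: StageTrajectory,
    model: ResponseModel | None = None,
    *,
    session: str = "pitch",
    radius_m: float = 0.1,
    frame_rate: float = 10.0,
    seed: int = 0,
    integration_rate: float = 200.0,
) -> TruthTraces:
    """Ground-truth green-channel response time courses for every cell.

    The red channel is activity-independent (trace applies to green only).
    A flat trajectory yields identically zero traces.
    """
    if session not in SESSION_AXES:
        raise ValueError(f"session must be one of {sorted(SESSION_AXES)}")
    model = model or ResponseModel()
    axis = SESSION_AXES[session]
    rng = np.random.default_rng(seed)

    pol = layout.cells[["pol_rc", "pol_ml"]].to_numpy()
    c = pol @ axis                         # polarity projection on session axis
    striolar = layout.cells.striolar.to_numpy()
    g_tilt = np.where(striolar, model.tilt_gain_striola,
                      model.tilt_gain_extrastriola)
    g_vib = np.where(striolar, model.vibration_gain_striola,
                     model.vibration_gain_extrastriola)
    biphasic = rng.uniform(size=layout.n) < model.biphasic_fraction

    # bin-average the drive onto the integration grid
    step = max(1, int(round(traj.sample_rate / integration_rate)))
    dt = step / traj.sample_rate
    n_bins = len(traj.t) // step
    s = np.sin(np.deg2rad(traj.theta))[: n_bins * step].reshape(n_bins, step).mean(1)
    a_tan = np.abs(inertial_acceleration(traj, radius_m).tangential) / G0
    a_tan = a_tan[: n_bins * step].reshape(n_bins, step).mean(1)
    tb = (np.arange(n_bins) + 0.5) * dt

    proj = c[:, None] * s[None, :]         # (n, nb) p·a in g
    drive_tilt = g_tilt[:, None] * np.maximum(proj, 0.0)
    drive_tilt -= (model.negative_lobe_ratio * g_tilt * biphasic)[:, None] \
        * np.maximum(-proj, 0.0)

    # leaky accumulation of the projected vibration drive
    v = np.zeros(layout.n)
    k_in = g_vib * np.abs(c)
    drive = np.empty((layout.n, n_bins))
    adapt = np.zeros(layout.n)
    F = np.zeros(layout.n)
    out = np.empty((layout.n, n_bins))
    r_up = dt / model.indicator_rise_tau
    r_dn = dt / model.indicator_decay_tau
    for j in range(n_bins):
        v += dt * (k_in * a_tan[j] - v / model.vibration_tau)
        d = drive_tilt[:, j] + v
        if model.adapt_tau is not None:
            adapt += dt * (d - adapt) / model.adapt_tau
            d = d - (1.0 - model.adapt_persist) * adapt
        drive[:, j] = d
        rate = np.where(d > F, r_up, r_dn)
        F += np.clip(rate, 0, 1) * (d - F)
        out[:, j] = F

    t_frames = np.arange(0, traj.duration + 1e-9, 1.0 / frame_rate)
    traces = np.empty((layout.n, len(t_frames)))
    for i in range(layout.n):
        traces[i] = np.interp(t_frames, tb, out[i], left=0.0, right=out[i, -1])
    return TruthTraces(t=t_frames, traces=traces, biphasic=biphasic,
                       session=session, protocol=traj.protocol)


# ---------------------------------------------------------------------------
# artifacts and rendering


@dataclass
class ArtifactModel:
    """Optical/camera artifact model for rendered stacks.

    ``gain_excursion`` sets the peak deviation of the smooth multiplicative
    gain field from 1; ``common_mode_fraction`` is the fraction of the
    channel-specific deviation replaced by the shared field, so 1.0 makes
    both channels identical and 0 fully independent.
    """

    common_mode_fraction: float = 0.98
    gain_excursion: float = 0.5
    n_bumps: int = 4
    channel_noise_sd: float = 0.01
    n_hot_pixels: int = 3
    hot_value: float = 60000.0
    hot_pixels: list | None = None   # explicit (sensor_row, col, value) triples
    bleach_slope_green: float = 0.0  # fraction per second
    bleach_slope_red: float = 0.0
    background_level: float = 100.0
    photon_noise: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.common_mode_fraction <= 1:
            raise ValueError("common_mode_fraction must be in [0, 1]")

    @staticmethod
    def disabled() -> "ArtifactModel":
        return ArtifactModel(gain_excursion=0.0, channel_noise_sd=0.0,
                             n_hot_pixels=0, background_level=0.0,
                             photon_noise=False)


def _bump_field(shape, rng, n_bumps, excursion):
    """Smooth zero-mean field with peak |value| = excursion."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    f = np.zeros(shape, dtype=float)
    for _ in range(n_bumps):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sig = rng.uniform(0.25, 0.55) * min(h, w)
        amp = rng.uniform(-1.0, 1.0)
        f += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    peak = np.abs(f).max()
    if peak > 0:
        f *= excursion / peak
    return f


def build_gain_fields(artifact: ArtifactModel, shape, rng):
    """Per-channel multiplicative gain fields over the static camera frame."""
    if artifact.gain_excursion == 0:
        ones = np.ones(shape)
        return ones, ones.copy()
    common = _bump_field(shape, rng, artifact.n_bumps, artifact.gain_excursion)
    spec_g = _bump_field(shape, rng, artifact.n_bumps, artifact.gain_excursion)
    spec_r = _bump_field(shape, rng, artifact.n_bumps, artifact.gain_excursion)
    c = artifact.common_mode_fraction
    gain_g = 1.0 + common + (1.0 - c) * spec_g
    gain_r = 1.0 + common + (1.0 - c) * spec_r
    return np.clip(gain_g, 0.05, None), np.clip(gain_r, 0.05, None)


@dataclass
class Acquisition:
    """Camera/optics parameters of a rendered stack."""

    fov: tuple = (448, 456)
    pixel_size_um: float = 1.0 / 3.4
    frame_rate: float = 10.0
    rotation_center: tuple | None = None  # (row, col); default near frame center
    channel_offset: tuple = (0, 0)        # red-vs-green (drow, dcol) on the sensor

    def center(self) -> np.ndarray:
        if self.rotation_center is not None:
            return np.asarray(self.rotation_center, dtype=float)
        return np.array([(self.fov[0] - 1) / 2.0 + 0.4,
                         (self.fov[1] - 1) / 2.0 - 0.7])


@dataclass
class TwoChannelStack:
    """Time-series green/red image data with acquisition metadata."""

    green: np.ndarray   # (T, H, W)
    red: np.ndarray
    pixel_size_um: float
    frame_rate: float
    angle_per_frame: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def shape(self) -> tuple:
        return self.green.shape

    def to_wview(self) -> np.ndarray:
        """Combined raw export: green stacked above red, per frame."""
        return np.concatenate([self.green, self.red], axis=1)

    def save_tiff(self, path, wview: bool = True) -> None:
        import tifffile

        data = self.to_wview() if wview else np.stack([self.green, self.red], 1)
        tifffile.imwrite(path, data.astype(np.uint16))
        meta = dict(self.metadata, pixel_size_um=self.pixel_size_um,
                    frame_rate=self.frame_rate, wview=wview,
                    angle_per_frame=list(np.round(self.angle_per_frame, 6)))
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)


def bead_sources(beads: BeadField) -> pd.DataFrame:
    return pd.DataFrame({
        "source_id": np.arange(beads.n),
        "row_off": beads.offsets_px[:, 0],
        "col_off": beads.offsets_px[:, 1],
        "green": beads.green,
        "red": beads.red,
        "sigma_px": np.full(beads.n, beads.sigma_px),
    })


def layout_sources(
    layout: MaculaLayout,
    acq: Acquisition,
    *,
    session: str = "pitch",
    flux: float = 160000.0,
) -> pd.DataFrame:
    """Map anatomical cell positions into camera pixel offsets.

    Convention (left side, ventral view, pitch session): image rows increase
    caudally, columns increase laterally.  Right-side specimens are mirrored
    in columns.  For roll sessions the fish is yawed 90° so the tilted axis
    stays tangential in the camera: anatomical axes rotate accordingly.
    """
    s = 1.0 / acq.pixel_size_um
    x = layout.cells.x_rc.to_numpy()
    y = layout.cells.y_ml.to_numpy()
    if layout.side == "right":
        y = -y
    if session == "pitch":
        row, col = -x * s, y * s
    elif session == "roll":
        row, col = -y * s, -x * s   # fish yawed 90°
    else:
        raise ValueError("session must be 'pitch' or 'roll'")
    sig = 0.4 * layout.cells.soma_radius_um.to_numpy() * s
    return pd.DataFrame({
        "source_id": layout.cells.cell_id.to_numpy(),
        "row_off": row,
        "col_off": col,
        "green": flux,
        "red": flux,
        "sigma_px": sig,
    })


def _render_spot(canvas, row, col, flux, sigma):
    """Add an integrated (pixel-exact) Gaussian spot to a frame in place."""
    h, w = canvas.shape
    r = int(np.ceil(4 * sigma)) + 1
    r0, r1 = int(np.floor(row)) - r, int(np.floor(row)) + r + 1
    c0, c1 = int(np.floor(col)) - r, int(np.floor(col)) + r + 1
    r0c, r1c = max(r0, 0), min(r1, h)
    c0c, c1c = max(c0, 0), min(c1, w)
    if r0c >= r1c or c0c >= c1c:
        return
    s2 = sigma * np.sqrt(2.0)
    ys = np.arange(r0c, r1c)
    xs = np.arange(c0c, c1c)
    fy = 0.5 * (erf((ys + 0.5 - row) / s2) - erf((ys - 0.5 - row) / s2))
    fx = 0.5 * (erf((xs + 0.5 - col) / s2) - erf((xs - 0.5 - col) / s2))
    canvas[r0c:r1c, c0c:c1c] += flux * fy[:, None] * fx[None, :]


def render_stack(
    sources: pd.DataFrame,
    traj: StageTrajectory,
    *,
    traces: TruthTraces | np.ndarray | None = None,
    artifact: ArtifactModel | None = None,
    acq: Acquisition | None = None,
    seed: int = 0,
    metadata: dict | None = None,
) -> TwoChannelStack:
    """Render a rotating two-channel stack at the camera frame rate.

    Each frame places every source at its position rotated by the stage
    angle about the rotation center, modulates green by the truth trace,
    multiplies both channels by the static-frame gain fields, applies
    bleaching, per-frame channel gain noise, background, optional Poisson
    noise, and burns in hot pixels.  Identical seeds give identical stacks.
    """
    artifact = artifact if artifact is not None else ArtifactModel()
    acq = acq or Acquisition()
    rng = np.random.default_rng(seed)
    h, w = acq.fov
    center = acq.center()
    if np.any(center < 0) or center[0] >= h or center[1] >= w:
        import warnings

        warnings.warn("rotation center lies outside the frame")

    t_frames = np.arange(0, traj.duration + 1e-9, 1.0 / acq.frame_rate)
    theta = np.interp(t_frames, traj.t, traj.theta)
    T = len(t_frames)

    tr = None
    if traces is not None:
        arr = traces.traces if isinstance(traces, TruthTraces) else np.asarray(traces)
        if arr.shape[0] != len(sources):
            raise ValueError("traces and sources disagree on source count")
        if arr.shape[1] != T:
            raise ValueError("traces not sampled at the camera frame times")
        tr = arr

    gain_g, gain_r = build_gain_fields(artifact, (h, w), rng)
    noise_g = 1.0 + artifact.channel_noise_sd * rng.standard_normal(T)
    noise_r = 1.0 + artifact.channel_noise_sd * rng.standard_normal(T)

    hp = artifact.hot_pixels
    if hp is None and artifact.n_hot_pixels > 0:
        rows = rng.integers(0, 2 * h, artifact.n_hot_pixels)
        cols = rng.integers(0, w, artifact.n_hot_pixels)
        hp = [(int(r), int(c), artifact.hot_value) for r, c in zip(rows, cols)]
    hp = hp or []

    off = sources[["row_off", "col_off"]].to_numpy()
    fg = sources.green.to_numpy()
    fr = sources.red.to_numpy()
    sig = sources.sigma_px.to_numpy()

    green = np.empty((T, h, w), dtype=np.float32)
    red = np.empty((T, h, w), dtype=np.float32)
    for j in range(T):
        th = np.deg2rad(theta[j])
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pos = off @ rot.T + center
        cg = np.zeros((h, w))
        cr = np.zeros((h, w))
        for i in range(len(off)):
            amp = fg[i] * (1.0 + (tr[i, j] if tr is not None else 0.0))
            _render_spot(cg, pos[i, 0], pos[i, 1], max(amp, 0.0), sig[i])
            _render_spot(cr, pos[i, 0], pos[i, 1], fr[i], sig[i])
        ts = t_frames[j]
        cg *= gain_g * noise_g[j] * (1.0 + artifact.bleach_slope_green * ts)
        cr *= gain_r * noise_r[j] * (1.0 + artifact.bleach_slope_red * ts)
        cg += artifact.background_level
        cr += artifact.background_level
        if artifact.photon_noise:
            cg = rng.poisson(np.clip(cg, 0, None)).astype(np.float64)
            cr = rng.poisson(np.clip(cr, 0, None)).astype(np.float64)
        for (hr, hc, hv) in hp:
            if hr < h:
                cg[hr, hc] = hv
            elif hr < 2 * h:
                cr[hr - h, hc] = hv
        green[j] = np.clip(cg, 0, 65535)
        red[j] = np.clip(cr, 0, 65535)

    meta = dict(metadata or {})
    meta.update(protocol=traj.protocol, seed=seed,
                rotation_center=list(center),
                hot_pixels=[list(p) for p in hp])
    return TwoChannelStack(green=green, red=red,
                           pixel_size_um=acq.pixel_size_um,
                           frame_rate=acq.frame_rate,
                           angle_per_frame=theta,
                           metadata=meta)


# ---------------------------------------------------------------------------
# photoconversion volumes


def make_photoconversion_volume(
    shape: tuple = (24, 48, 64),
    gradient_axis: int = 2,
    seed: int = 0,
    *,
    ratio_range: tuple = (2.0, 0.5),
    fiber_fraction: float = 0.3,
    green_level: float = 1000.0,
    background: float = 60.0,
    photon_noise: bool = True,
):
    """3-D two-channel volume with a red/green ratio gradient in a mask.

    Inside an ellipsoidal "utricle" mask, a fraction of voxels (smooth
    seeded blobs emulating neuronal processes) carries bright green signal;
    red = green × ratio, where the ratio ramps linearly from
    ``ratio_range[0]`` to ``ratio_range[1]`` along ``gradient_axis``
    (normalized to the mask extent) and is uniform along the other axes.

    Returns (volume, mask, fiber_mask, truth) where volume is (2, Z, Y, X)
    green/red and truth maps normalized axis position to the ground-truth
    ratio.
    """
    shape = tuple(shape)
    if min(shape) < 16:
        raise ValueError("each axis must have at least 16 voxels")
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]].astype(float)
    cz, cy, cx = [(s - 1) / 2.0 for s in shape]
    mask = ((zz - cz) / (0.45 * shape[0])) ** 2 + \
           ((yy - cy) / (0.45 * shape[1])) ** 2 + \
           ((xx - cx) / (0.45 * shape[2])) ** 2 <= 1.0

    # fibrous structure: threshold a smoothed random field at the requested fill
    from scipy.ndimage import gaussian_filter

    noise = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    thr = np.quantile(noise[mask], 1.0 - fiber_fraction)
    fiber = mask & (noise > thr)

    coord = (zz, yy, xx)[gradient_axis]
    lo, hi = coord[mask].min(), coord[mask].max()
    u = np.clip((coord - lo) / max(hi - lo, 1), 0.0, 1.0)
    r0, r1 = ratio_range
    ratio = r0 + (r1 - r0) * u

    green = np.where(fiber, green_level, 0.0) + background
    red = np.where(fiber, green_level * ratio, 0.0) + background
    if photon_noise:
        green = rng.poisson(green).astype(float)
        red = rng.poisson(red).astype(float)
    volume = np.stack([green, red])

    def truth(u_norm):
        return r0 + (r1 - r0) * np.asarray(u_norm, dtype=float)

    return volume, mask, fiber, truth
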