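"""Response quantification, classification and vector-field mapping.

Amplitudes (all in % ΔR/R0):

* hair-cell ±90° tilt — mean ΔR/R0 over the full hold plateau of each tilt
  direction (hair-cell responses stay constant during the hold);
* vestibular-ganglion-neuron (VGN) tilt — mean ΔR/R0 in the closed window
  from 2 s before to 2 s after the tilt angle first reaches ±90° (VGN
  responses decay during the hold);
* vibration — mean ΔR/R0 over the last 4.5 s of stimulus-on time.

Cells count as activated when the largest positive amplitude exceeds 10%
(tilt) or 5% (vibration), strictly.  Preferred tilt direction is the
direction of the larger activating amplitude; hair cells with an
anti-preferred amplitude below −5% are biphasic; VGNs get a preferred
direction only when one direction responds more than twofold stronger than
the other.  Per-cell response vectors are the vector sum of the pitch and
roll amplitudes on the rostro-caudal / medio-lateral axes (positive =
nose-down / lateral-down), and multi-sample summaries average the vectors
on a square grid whose spacing equals the mean nearest-neighbor distance
between cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ratiometric import RoiTraceSet
from .stimulus import StageTrajectory

__all__ = [
    "TILT_THRESHOLD",
    "VIBRATION_THRESHOLD",
    "BIPHASIC_THRESHOLD",
    "tilt_amplitude_hc",
    "tilt_amplitude_vgn",
    "vibration_amplitude",
    "classify_activation",
    "classify_direction_hc",
    "classify_direction_vgn",
    "classify_vgn_groups",
    "response_vector",
    "vibration_vector",
    "responsivity_per_g",
    "build_grid",
    "grid_mean_vectors",
    "GridSummary",
    "amplitude_table",
]

TILT_THRESHOLD = 10.0        # % ΔR/R0, strict
VIBRATION_THRESHOLD = 5.0    # % ΔR/R0, strict
BIPHASIC_THRESHOLD = -5.0    # % ΔR/R0 on the anti-preferred side


def _frame_theta(traj: StageTrajectory, t_frames: np.ndarray) -> np.ndarray:
    return np.interp(t_frames, traj.t, traj.theta)


def _plateau_frames(theta, omega, target, tol=1.0):
    return np.nonzero((np.abs(theta - target) < tol) & (np.abs(omega) < 0.5))[0]


def tilt_amplitude_hc(trace_drr, t, traj: StageTrajectory):
    """Signed (+90°, −90°) amplitudes in % ΔR/R0, hair-cell windows."""
    if traj.protocol != "tilt90":
        raise ValueError("hair-cell tilt amplitudes need the tilt90 protocol")
    theta = _frame_theta(traj, t)
    omega = np.interp(t, traj.t, traj.omega)
    target = traj.params.get("angle", 90.0)
    amps = []
    for sign in (+1.0, -1.0):
        idx = _plateau_frames(theta, omega, sign * target)
        if len(idx) < 3:
            raise ValueError(
                f"hold plateau at {sign * target:+.0f}° shorter than 3 frames"
            )
        amps.append(100.0 * float(np.mean(np.asarray(trace_drr)[idx])))
    return tuple(amps)


def tilt_amplitude_vgn(trace_drr, t, traj: StageTrajectory, window_s: float = 2.0):
    """Signed (+90°, −90°) amplitudes, VGN windows centered on plateau onset.

    The window is the closed interval [t*−2 s, t*+2 s] around the instant
    the tilt angle first reaches each extreme; windows clipped by the
    recording are truncated and flagged.
    """
    if traj.protocol != "tilt90":
        raise ValueError("VGN tilt amplitudes need the tilt90 protocol")
    theta = _frame_theta(traj, t)
    target = traj.params.get("angle", 90.0)
    trace = np.asarray(trace_drr)
    amps, truncated = [], []
    for sign in (+1.0, -1.0):
        reach = np.nonzero(np.abs(theta - sign * target) < 1.0)[0]
        if len(reach) == 0:
            raise ValueError(f"tilt never reaches {sign * target:+.0f}°")
        t_star = t[reach[0]]
        m = (t >= t_star - window_s - 1e-9) & (t <= t_star + window_s + 1e-9)
        truncated.append(bool(t_star - window_s < t[0] - 1e-9
                              or t_star + window_s > t[-1] + 1e-9))
        amps.append(100.0 * float(trace[m].mean()))
    return tuple(amps), tuple(truncated)


def vibration_amplitude(trace_drr, t, traj: StageTrajectory,
                        window_s: float = 4.5) -> float:
    """Mean ΔR/R0 (%) over the last ``window_s`` of stimulus-on time."""
    if traj.protocol != "vibration":
        raise ValueError("vibration amplitude needs the vibration protocol")
    t_on0 = traj.first_motion_time()
    t_on1 = traj.last_motion_time()
    if t_on1 - t_on0 < window_s:
        raise ValueError(f"stimulus shorter than {window_s} s")
    m = (t >= t_on1 - window_s - 1e-9) & (t <= t_on1 + 1e-9)
    return 100.0 * float(np.asarray(trace_drr)[m].mean())


def classify_activation(amplitudes, stimulus: str) -> bool:
    """Strict-threshold activation: >10% for tilt, >5% for vibration."""
    thr = {"tilt": TILT_THRESHOLD, "vibration": VIBRATION_THRESHOLD}[stimulus]
    return bool(np.max(amplitudes) > thr)


def classify_direction_hc(amp_plus: float, amp_minus: float,
                          labels=("plus", "minus")):
    """Preferred direction and response shape for one hair-cell session.

    Returns (direction, shape, ambiguous): direction is the label of the
    larger activating amplitude (or None); shape is 'biphasic' when the
    anti-preferred amplitude is below −5%, 'monophasic' otherwise.
    """
    act_p = amp_plus > TILT_THRESHOLD
    act_m = amp_minus > TILT_THRESHOLD
    ambiguous = act_p and act_m
    if not (act_p or act_m):
        return None, "n/a", False
    if amp_plus >= amp_minus:
        direction, anti = labels[0], amp_minus
    else:
        direction, anti = labels[1], amp_plus
    shape = "biphasic" if anti < BIPHASIC_THRESHOLD else "monophasic"
    return direction, shape, ambiguous


def classify_direction_vgn(amp_plus: float, amp_minus: float,
                           labels=("plus", "minus")):
    """VGN preferred direction under the twofold rule.

    A direction is assigned only if it activates (>10%) and its amplitude
    exceeds twice the opposite one (opposite clipped at 0).
    """
    for amp, opp, lab in ((amp_plus, amp_minus, labels[0]),
                          (amp_minus, amp_plus, labels[1])):
        if amp > TILT_THRESHOLD and amp > 2.0 * max(opp, 0.0):
            return lab
    return None


def classify_vgn_groups(tilt_activated: bool, vibration_activated: bool) -> str:
    if tilt_activated and vibration_activated:
        return "tilt_and_vibration"
    if tilt_activated:
        return "tilt_selective"
    if vibration_activated:
        return "vibration_selective"
    return "nonresponsive"


def response_vector(pitch_amps, roll_amps):
    """Preferred/anti-preferred tilt response vectors from both sessions.

    ``pitch_amps`` = (nose_down, tail_down) %, ``roll_amps`` =
    (lateral_down, medial_down) %.  Axis convention: +rc = rostral
    (nose-down), +ml = lateral (lateral-down).  The preferred vector takes
    the positive amplitude of each session's stronger direction; the
    anti-preferred vector collects negative amplitudes, pointing toward the
    direction that suppressed the cell.  Length = √(rc² + ml²).
    """

    def axis_components(a_plus, a_minus):
        p_pos, m_pos = max(a_plus, 0.0), max(a_minus, 0.0)
        pref = p_pos if p_pos >= m_pos else -m_pos
        p_neg, m_neg = min(a_plus, 0.0), min(a_minus, 0.0)
        if p_neg == 0.0 and m_neg == 0.0:
            anti = 0.0
        elif abs(p_neg) >= abs(m_neg):
            anti = -p_neg   # suppressed by +direction → anti points +axis
        else:
            anti = m_neg
        return pref, anti

    pr, pa = axis_components(*pitch_amps)
    rr, ra = axis_components(*roll_amps)
    preferred = np.array([pr, rr])
    anti = np.array([pa, ra])
    length = float(np.hypot(*preferred))
    return preferred, anti, length


def vibration_vector(vib_pitch: float | None, vib_roll: float | None):
    """Axis-aligned vibration bars and their combined length.

    Bars keep their signed per-axis amplitudes; the combined length is the
    root-sum-square of the two.  ``None`` marks a session not run.
    """
    if vib_pitch is None and vib_roll is None:
        raise ValueError("at least one vibration axis must be measured")
    p = 0.0 if vib_pitch is None else vib_pitch
    r = 0.0 if vib_roll is None else vib_roll
    return np.array([p, r]), float(np.hypot(p, r))


def responsivity_per_g(max_amp: float, max_accel_g: float) -> float:
    """Maximum response amplitude per maximum in-plane acceleration, %/g."""
    if max_accel_g <= 0:
        raise ValueError("maximum acceleration must be positive")
    return max_amp / max_accel_g


# ---------------------------------------------------------------------------
# grids


@dataclass
class GridSummary:
    """Square grid with per-point mean vectors and assignment counts."""

    points: np.ndarray                    # (m, 2) µm
    interval: float                       # µm
    mean_vectors: np.ndarray | None = None
    counts: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def nonempty(self) -> np.ndarray:
        return self.counts > 0


def build_grid(positions: np.ndarray, sample_ids=None) -> GridSummary:
    """Square grid over the pooled bounding box.

    Spacing equals the mean, over cells, of the distance to the nearest
    neighbouring cell.  When ``sample_ids`` labels cells by sample
    (utricle/ganglion), neighbours are sought within the same sample only,
    so pooling aligned maps does not shrink the spacing.
    """
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 2:
        raise ValueError("need at least 2 positions")
    if sample_ids is None:
        sample_ids = np.zeros(len(pos))
    sample_ids = np.asarray(sample_ids)
    nn = np.empty(len(pos))
    for sid in np.unique(sample_ids):
        m = sample_ids == sid
        sub = pos[m]
        if len(sub) < 2:
            raise ValueError(f"sample {sid!r} has fewer than 2 cells")
        d, _ = cKDTree(sub).query(sub, k=2)
        nn[m] = d[:, 1]
    if np.any(nn == 0):
        raise ValueError("duplicate cell positions")
    interval = float(nn.mean())
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    xs = np.arange(lo[0], hi[0] + interval, interval)
    ys = np.arange(lo[1], hi[1] + interval, interval)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel()])
    return GridSummary(points=points, interval=interval)


def grid_mean_vectors(positions, vectors, grid: GridSummary) -> GridSummary:
    """Assign each cell to its nearest grid point and average the vectors.

    Ties (equidistant points) resolve to the lowest point index so pooling
    is deterministic.
    """
    pos = np.asarray(positions, dtype=float)
    vec = np.asarray(vectors, dtype=float)
    if len(pos) != len(vec):
        raise ValueError("positions and vectors disagree")
    d = np.linalg.norm(pos[:, None, :] - grid.points[None, :, :], axis=2)
    assign = np.argmin(d, axis=1)  # argmin returns the first (lowest) index
    m = len(grid.points)
    sums = np.zeros((m, vec.shape[1]))
    counts = np.zeros(m, dtype=int)
    np.add.at(sums, assign, vec)
    np.add.at(counts, assign, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts[:, None] > 0, sums / np.maximum(counts, 1)[:, None],
                         np.nan)
    return GridSummary(points=grid.points, interval=grid.interval,
                       mean_vectors=means, counts=counts)


# ---------------------------------------------------------------------------
# convenience: per-cell amplitude/classification tables


def amplitude_table(
    pitch: RoiTraceSet,
    roll: RoiTraceSet,
    traj: StageTrajectory,
    *,
    cell_kind: str = "hc",
) -> pd.DataFrame:
    """Per-cell signed tilt amplitudes for a pitch + roll session pair.

    Columns: nose_down, tail_down, lateral_down, medial_down (% ΔR/R0),
    plus activation, preferred direction, shape and vector components.
    """
    if pitch.n != roll.n:
        raise ValueError("sessions measure different cell sets")
    rows = []
    for i in range(pitch.n):
        if cell_kind == "hc":
            nd, td = tilt_amplitude_hc(pitch.drr[i], pitch.t, traj)
            ld, md = tilt_amplitude_hc(roll.drr[i], roll.t, traj)
        else:
            (nd, td), _ = tilt_amplitude_vgn(pitch.drr[i], pitch.t, traj)
            (ld, md), _ = tilt_amplitude_vgn(roll.drr[i], roll.t, traj)
        activated = classify_activation([nd, td, ld, md], "tilt")
        if cell_kind == "hc":
            dp, shp_p, _ = classify_direction_hc(nd, td, ("nose_down", "tail_down"))
            dr, shp_r, _ = classify_direction_hc(ld, md,
                                                 ("lateral_down", "medial_down"))
            shapes = [s for s in (shp_p, shp_r) if s != "n/a"]
            shape = "biphasic" if "biphasic" in shapes else (
                "monophasic" if shapes else "n/a")
        else:
            dp = classify_direction_vgn(nd, td, ("nose_down", "tail_down"))
            dr = classify_direction_vgn(ld, md, ("lateral_down", "medial_down"))
            shape = "n/a"
        amps = {"nose_down": nd, "tail_down": td,
                "lateral_down": ld, "medial_down": md}
        cand = [d for d in (dp, dr) if d is not None]
        direction = max(cand, key=lambda d: amps[d]) if cand else "none"
        pref, anti, length = response_vector((nd, td), (ld, md))
        rows.append(dict(
            cell_id=pitch.roi_ids[i],
            nose_down=nd, tail_down=td, lateral_down=ld, medial_down=md,
            tilt_activated=activated, tilt_direction=direction, shape=shape,
            pref_rc=pref[0], pref_ml=pref[1],
            anti_rc=anti[0], anti_ml=anti[1], length=length,
        ))
    return pd.DataFrame(rows)
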