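"""Registration of rotating two-channel stacks.

Raw recordings arrive with the scene rotating about a fixed center (the
camera does not move with the stage).  The chain implemented here mirrors
the analysis the microscope requires:

1. split the combined "W-view" export (green above red) into channels;
2. repair hot pixels (constant-value sensor defects that smear into arcs
   once the rotation is corrected);
3. estimate the per-frame rotation angle and the rotation center from
   fluorescent-bead recordings by least-squares rigid fitting of tracked
   bead positions;
4. counter-rotate every frame (bilinear), carrying a valid-pixel mask;
5. refine residual drift: a similarity (rotation/scale) pass against a
   temporal-median reference, then translation by phase correlation with
   Fourier upsampling at the 1/10-pixel level;
6. subtract the first-percentile background of a non-fluorescent region;
7. mirror/translate per-sample maps into a common anatomical frame.

Bead-derived rotation sequences can be reused for fish stacks recorded
with the same stimulus, exactly as done at the instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import warp_polar

from .synthetic import TwoChannelStack

__all__ = [
    "RotationEstimate",
    "RegisteredStack",
    "HotPixelReport",
    "split_channels",
    "repair_hot_pixels",
    "detect_beads",
    "estimate_rotation",
    "derotate_stack",
    "refine_registration",
    "subtract_background",
    "SampleMap",
    "align_across_samples",
]


# ---------------------------------------------------------------------------
# channel splitting


def split_channels(
    raw: np.ndarray,
    vertical_offset: int = 0,
    horizontal_offset: int = 0,
    **stack_kwargs,
) -> TwoChannelStack:
    """Split a W-view stack (green on top, red below) into channels.

    ``vertical_offset``/``horizontal_offset`` are the manual red-vs-green
    alignment offsets applied at acquisition; the red half is shifted back
    by them.  Frames may be a single image (H*2, W) or a stack (T, H*2, W).
    """
    raw = np.asarray(raw)
    if raw.ndim == 2:
        raw = raw[None]
    H2 = raw.shape[1]
    if H2 % 2 and vertical_offset == 0 and horizontal_offset == 0:
        raise ValueError("frame height is odd; provide alignment offsets")
    h = H2 // 2
    if abs(vertical_offset) >= h // 2 or abs(horizontal_offset) >= raw.shape[2] // 2:
        raise ValueError("offsets push the channels out of overlap")
    green = raw[:, :h].astype(np.float32)
    red = raw[:, h : 2 * h].astype(np.float32)
    if vertical_offset or horizontal_offset:
        red = np.roll(red, (-vertical_offset, -horizontal_offset), axis=(1, 2))
    return TwoChannelStack(
        green=green,
        red=red,
        pixel_size_um=stack_kwargs.pop("pixel_size_um", 1.0 / 3.4),
        frame_rate=stack_kwargs.pop("frame_rate", 10.0),
        angle_per_frame=stack_kwargs.pop(
            "angle_per_frame", np.zeros(raw.shape[0])
        ),
        metadata=stack_kwargs.pop("metadata", {}),
    )


# ---------------------------------------------------------------------------
# hot pixels


@dataclass
class HotPixelReport:
    coords_green: list
    coords_red: list
    n_pixels: int
    fraction: float


def _repair_channel(frames: np.ndarray, coords) -> None:
    """Replace flagged pixels, per frame, by the median of their unflagged
    3×3 neighbours (center excluded)."""
    flagged = set(map(tuple, coords))
    T, h, w = frames.shape
    for (r, c) in coords:
        nb = [
            (rr, cc)
            for rr in range(max(r - 1, 0), min(r + 2, h))
            for cc in range(max(c - 1, 0), min(c + 2, w))
            if (rr, cc) != (r, c) and (rr, cc) not in flagged
        ]
        if not nb:
            continue
        vals = np.stack([frames[:, rr, cc] for rr, cc in nb], axis=1)
        frames[:, r, c] = np.median(vals, axis=1)


def _detect_channel(frames: np.ndarray) -> np.ndarray:
    """Hot pixels: (near) zero temporal variance at an intensity above the
    99.9th percentile of the median frame."""
    sd = frames.std(axis=0)
    med = np.median(frames, axis=0)
    bright = med > np.percentile(med, 99.9)
    return np.argwhere((sd < 0.5) & bright)


def repair_hot_pixels(
    stack: TwoChannelStack,
    detection: str = "auto",
    mask_green=None,
    mask_red=None,
) -> tuple[TwoChannelStack, HotPixelReport]:
    """Detect and repair hot pixels in both channels (in place on copies)."""
    if detection == "auto":
        if stack.n_frames < 3:
            raise ValueError("auto detection needs at least 3 frames")
        cg = _detect_channel(stack.green)
        cr = _detect_channel(stack.red)
    elif detection == "mask":
        cg = np.argwhere(mask_green) if mask_green is not None else np.empty((0, 2), int)
        cr = np.argwhere(mask_red) if mask_red is not None else np.empty((0, 2), int)
    else:
        raise ValueError("detection must be 'auto' or 'mask'")
    green = stack.green.copy()
    red = stack.red.copy()
    _repair_channel(green, cg)
    _repair_channel(red, cr)
    n = len(cg) + len(cr)
    npix = 2 * stack.green.shape[1] * stack.green.shape[2]
    frac = n / npix
    if frac > 0.001:
        warnings.warn(
            f"{frac:.2%} of pixels flagged as hot; detection looks suspicious"
        )
    rep = HotPixelReport(
        coords_green=[tuple(map(int, c)) for c in cg],
        coords_red=[tuple(map(int, c)) for c in cr],
        n_pixels=n,
        fraction=frac,
    )
    out = TwoChannelStack(
        green=green, red=red, pixel_size_um=stack.pixel_size_um,
        frame_rate=stack.frame_rate, angle_per_frame=stack.angle_per_frame,
        metadata=dict(stack.metadata),
    )
    return out, rep


# ---------------------------------------------------------------------------
# bead detection and rotation estimation


def detect_beads(frame: np.ndarray, min_area: int = 3,
                 rel_threshold: float = 0.3) -> pd.DataFrame:
    """Subpixel bead/soma centroids from one frame.

    The threshold adapts to the scene: background + max(5 robust sigmas,
    ``rel_threshold`` × the background-subtracted 99.9th percentile), which
    keeps the detected components compact for big soma-sized spots so
    neighbours stay separable.  Components touching the border are dropped;
    components with more than one internal intensity peak are flagged as
    merged.  Centroids are intensity-weighted centers of mass.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    bg = np.median(frame)
    sigma = 1.4826 * np.median(np.abs(frame - bg)) + 1e-12
    high = np.percentile(frame, 99.9) - bg
    thr = bg + max(5.0 * sigma, rel_threshold * high)
    binary = frame > thr
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no beads found above threshold")
    border = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
    border.discard(0)
    signal = np.clip(frame - bg, 0, None)
    peaks = (ndimage.maximum_filter(frame, size=3) == frame) & binary
    # adjacent tied maxima (e.g. a spot centered on a pixel boundary) are one peak
    peak_labels, _ = ndimage.label(peaks, structure=np.ones((3, 3)))
    slices = ndimage.find_objects(labels)
    rows = []
    for lab in range(1, n + 1):
        if lab in border:
            continue
        sl = slices[lab - 1]
        m = labels[sl] == lab
        area = int(m.sum())
        if area < min_area:
            continue
        w = signal[sl] * m
        tot = w.sum()
        rr, cc = np.nonzero(m)
        wv = w[rr, cc]
        row = float((rr * wv).sum() / tot) + sl[0].start
        col = float((cc * wv).sum() / tot) + sl[1].start
        pl = peak_labels[sl][m]
        n_peaks = len(np.unique(pl)) - (0 if pl.all() else 1)
        # merged sub-2σ pairs show a single elongated blob: use the ratio of
        # principal second moments as a second criterion
        dy, dx = rr - (row - sl[0].start), cc - (col - sl[1].start)
        cyy = (wv * dy * dy).sum() / tot
        cxx = (wv * dx * dx).sum() / tot
        cxy = (wv * dy * dx).sum() / tot
        tr_half = (cyy + cxx) / 2.0
        det_c = cyy * cxx - cxy**2
        disc = max(tr_half**2 - det_c, 0.0)
        lam1 = tr_half + np.sqrt(disc)
        lam2 = max(tr_half - np.sqrt(disc), 1e-12)
        merged = n_peaks > 1 or (area >= 6 and lam1 / lam2 > 1.45)
        rows.append((row, col, float(tot), area, merged))
    if not rows:
        raise ValueError("no beads found away from the border")
    return pd.DataFrame(rows, columns=["row", "col", "intensity", "area", "merged"])


@dataclass
class RotationEstimate:
    """Per-frame rotation angle and the (measured) rotation center."""

    angle_per_frame: np.ndarray   # degrees, unwrapped
    center: np.ndarray            # (row, col)
    residual_rms: float           # px
    n_beads_used: np.ndarray      # per frame
    flags: np.ndarray             # frames where the angle was held
    ambiguous: bool = False


def _rigid_fit(ref: np.ndarray, cur: np.ndarray):
    """LSQ rigid transform ref→cur: returns (angle_rad, R, t)."""
    mr = ref.mean(axis=0)
    mc = cur.mean(axis=0)
    a = ref - mr
    b = cur - mc
    num = (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]).sum()
    den = (a * b).sum()
    th = np.arctan2(num, den)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = mc - R @ mr
    return th, R, t


def estimate_rotation(
    stack: TwoChannelStack | np.ndarray,
    *,
    center: tuple | None = None,
    gate_factor: float = 3.0,
) -> RotationEstimate:
    """Estimate per-frame rotation from tracked bead positions.

    Beads are tracked frame-to-frame by mutual nearest neighbours (gate:
    ``gate_factor`` × median displacement).  Each frame's rotation angle and
    the common rotation center come from a least-squares rigid fit of the
    reference-frame bead constellation onto the current one; the center is
    then fixed and angles re-fit about it.  Angles are unwrapped over time.
    """
    frames = stack.green if isinstance(stack, TwoChannelStack) else np.asarray(stack)
    T = frames.shape[0]
    ref_df = detect_beads(frames[0])
    # merged components are still stable landmarks (their centroid rotates
    # with the scene); prefer clean ones but never drop below 8 points
    clean = ref_df[~ref_df.merged]
    ref_df = clean if len(clean) >= min(8, len(ref_df)) else ref_df
    ref = ref_df[["row", "col"]].to_numpy()
    if len(ref) < 1:
        raise ValueError("no trackable beads in the reference frame")
    single = len(ref) < 2
    if single and center is None:
        raise ValueError(
            "a single bead constrains only the angle; provide a fixed center"
        )

    c_pred = (np.asarray(center, dtype=float) if center is not None
              else (np.array(frames.shape[1:], dtype=float) - 1) / 2.0)
    positions = np.full((T, len(ref), 2), np.nan)
    positions[0] = ref
    angles = np.zeros(T)
    flags = np.zeros(T, bool)
    centers = []
    for j in range(1, T):
        try:
            det = detect_beads(frames[j])
        except ValueError:
            flags[j] = True
            angles[j] = angles[j - 1]
            continue
        cur_clean = det[~det.merged]
        cur = (cur_clean if len(cur_clean) >= min(8, len(det)) else det)[
            ["row", "col"]].to_numpy()
        if len(cur) == 0:
            flags[j] = True
            angles[j] = angles[j - 1]
            continue
        # predict the constellation from extrapolated rotation (delta capped
        # at the protocol-level 10°/frame continuity bound), then match
        delta = np.clip(angles[j - 1] - angles[j - 2], -10.0, 10.0) \
            if j >= 2 else 0.0
        th_pred = angles[j - 1] + delta
        pred = (ref - c_pred) @ _rotmat(th_pred).T + c_pred
        d = np.linalg.norm(pred[:, None, :] - cur[None, :, :], axis=2)
        fwd = d.argmin(axis=1)
        bwd = d.argmin(axis=0)
        match_d = d[np.arange(len(pred)), fwd]
        mutual = bwd[fwd] == np.arange(len(pred))
        if mutual.any():
            gate = gate_factor * max(float(np.median(match_d[mutual])), 1.0)
        else:
            gate = np.inf
        ok = mutual & (match_d <= gate)
        if ok.sum() < (1 if single else 2):
            flags[j] = True
            angles[j] = angles[j - 1]
            continue
        th, R, t = _rigid_fit(ref[ok], cur[fwd[ok]])
        rms = np.sqrt(np.mean(np.sum(
            (ref[ok] @ R.T + t - cur[fwd[ok]]) ** 2, axis=1)))
        raw = np.degrees(th)
        # unwrap online to the predicted branch
        cand = raw + 360.0 * np.round((th_pred - raw) / 360.0)
        if rms > 3.0 or abs(cand - angles[j - 1]) > 10.0:
            # bad fit or discontinuous: hold the previous angle
            flags[j] = True
            angles[j] = angles[j - 1]
            continue
        positions[j, ok] = cur[fwd[ok]]
        angles[j] = cand
        if abs(angles[j]) > 2.0 and ok.sum() >= 2:
            centers.append(np.linalg.solve(np.eye(2) - R, t))

    n_used = np.sum(~np.isnan(positions[:, :, 0]), axis=1)
    if np.all(n_used[1:] < (1 if single else 2)):
        raise ValueError("tracking lost on all beads")

    if center is not None:
        c = np.asarray(center, dtype=float)
    elif centers:
        c = np.median(np.array(centers), axis=0)
    else:
        # no frame rotated enough to localize the center; fall back to image
        c = (np.array(frames.shape[1:], dtype=float) - 1) / 2.0

    # second pass: angles about the fixed center
    ref_c = ref - c
    resid = []
    for j in range(T):
        m = ~np.isnan(positions[j, :, 0])
        if m.sum() < (1 if single else 2):
            angles[j] = angles[j - 1] if j else 0.0
            flags[j] = True
            continue
        cur_c = positions[j][m] - c
        a = ref_c[m]
        num = (a[:, 0] * cur_c[:, 1] - a[:, 1] * cur_c[:, 0]).sum()
        den = (a * cur_c).sum()
        raw = np.degrees(np.arctan2(num, den))
        prev = angles[j]  # first-pass estimate carries the branch
        angles[j] = raw + 360.0 * np.round((prev - raw) / 360.0)
        R = _rotmat(angles[j])
        resid.append(np.sqrt(np.mean(np.sum((a @ R.T - cur_c) ** 2, axis=1))))
    # symmetric 2-point constellations make 180° rotations ambiguous
    ambiguous = False
    if len(ref) == 2:
        mid = ref.mean(axis=0)
        if np.linalg.norm(mid - c) < 1.0:
            ambiguous = True
    return RotationEstimate(
        angle_per_frame=angles, center=c,
        residual_rms=float(np.mean(resid)) if resid else 0.0,
        n_beads_used=n_used, flags=flags, ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# derotation and refinement


@dataclass
class RegisteredStack:
    """A counter-rotated, drift-corrected two-channel stack.

    ``transforms`` logs the applied per-frame rotation and translation;
    ``valid`` masks pixels that stayed inside the field for that frame.
    """

    green: np.ndarray
    red: np.ndarray
    valid: np.ndarray
    angle_applied: np.ndarray
    center: np.ndarray
    shifts: np.ndarray
    pixel_size_um: float
    frame_rate: float
    metadata: dict = field(default_factory=dict)
    background: tuple = (0.0, 0.0)

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def transforms(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "angle_deg": self.angle_applied,
            "center_row": self.center[0],
            "center_col": self.center[1],
            "dy_px": self.shifts[:, 0],
            "dx_px": self.shifts[:, 1],
        })

    def save_transforms(self, path) -> None:
        self.transforms.to_csv(path, index=False, float_format="%.6g")


def _rotmat(angle_deg: float) -> np.ndarray:
    th = np.radians(angle_deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


def derotate_stack(
    stack: TwoChannelStack,
    estimate: RotationEstimate,
) -> RegisteredStack:
    """Counter-rotate every frame about the estimated center (bilinear).

    Out-of-field pixels are filled with the frame's background estimate and
    excluded from the valid mask so downstream ROI measurements never see
    the filled corners.
    """
    angles = estimate.angle_per_frame
    if len(angles) != stack.n_frames:
        raise ValueError("estimate does not cover all frames")
    c = np.asarray(estimate.center, dtype=float)
    T, h, w = stack.green.shape
    green = np.empty_like(stack.green)
    red = np.empty_like(stack.red)
    valid = np.empty((T, h, w), dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    for j in range(T):
        A = _rotmat(angles[j])
        off = c - A @ c
        bg_g = float(np.percentile(stack.green[j, ::3, ::3], 1))
        bg_r = float(np.percentile(stack.red[j, ::3, ::3], 1))
        green[j] = ndimage.affine_transform(
            stack.green[j], A, offset=off, order=1, cval=bg_g, output=np.float32
        )
        red[j] = ndimage.affine_transform(
            stack.red[j], A, offset=off, order=1, cval=bg_r, output=np.float32
        )
        # valid = source coordinate (A·o + off) stays inside the frame,
        # with a 1-px guard for the bilinear support
        sr = A[0, 0] * rr + A[0, 1] * cc + off[0]
        sc = A[1, 0] * rr + A[1, 1] * cc + off[1]
        valid[j] = (sr >= 1) & (sr <= h - 2) & (sc >= 1) & (sc <= w - 2)
    return RegisteredStack(
        green=green, red=red, valid=valid,
        angle_applied=angles.copy(), center=c,
        shifts=np.zeros((T, 2)),
        pixel_size_um=stack.pixel_size_um, frame_rate=stack.frame_rate,
        metadata=dict(stack.metadata),
    )


def _reference_image(reg: RegisteredStack, ref_window: int | None) -> np.ndarray:
    n = ref_window if ref_window is not None else max(int(reg.frame_rate), 2)
    n = min(n, reg.n_frames)
    return np.median(reg.green[:n] + reg.red[:n], axis=0).astype(np.float64)


def refine_registration(
    reg: RegisteredStack,
    *,
    ref_window: int | None = None,
    upsample: int = 100,
    similarity: bool = True,
    min_correlation: float = 0.5,
) -> RegisteredStack:
    """Correct residual drift against a temporal-median reference.

    Pass 1 (optional): rotation/scale by phase correlation of log-polar
    magnitude spectra, applied only when the estimate is meaningfully
    nonzero.  Pass 2: translation by phase correlation with Fourier
    upsampling (default precision well below the 1/10-pixel target).
    Frames whose normalized correlation peak stays below
    ``min_correlation`` keep the previous frame's transform and are
    flagged.  All FFT work runs on a centered power-of-two crop.
    """
    ref = _reference_image(reg, ref_window)
    T = reg.n_frames
    green = reg.green.copy()
    red = reg.red.copy()
    valid = reg.valid.copy()
    shifts = reg.shifts.copy()
    angle = reg.angle_applied.copy()

    h, w = ref.shape
    side = 1 << int(np.floor(np.log2(min(h, w))))
    r0, c0 = (h - side) // 2, (w - side) // 2
    crop = (slice(r0, r0 + side), slice(c0, c0 + side))
    ref_c = ref[crop]
    if similarity:
        ref_f = np.abs(np.fft.fftshift(np.fft.fft2(ref_c)))
        radius = side // 2
        n_angles = 720
        ref_pol = warp_polar(ref_f, radius=radius, output_shape=(n_angles, radius),
                             scaling="log", order=1)

    prev_shift = np.zeros(2)
    for j in range(T):
        img = (green[j] + red[j]).astype(np.float64)
        extra_rot = 0.0
        if similarity:
            for _ in range(3):  # iterate: log-polar estimates are coarse
                img_f = np.abs(np.fft.fftshift(np.fft.fft2(img[crop])))
                img_pol = warp_polar(img_f, radius=radius,
                                     output_shape=(n_angles, radius),
                                     scaling="log", order=1)
                sh, _, _ = phase_cross_correlation(
                    ref_pol, img_pol, upsample_factor=20, normalization=None
                )
                rot = sh[0] * 360.0 / n_angles
                if not 0.02 < abs(rot) < 1.0:
                    break
                extra_rot += rot
                A = _rotmat(rot)
                c = (np.array(img.shape, dtype=float) - 1) / 2.0
                off = c - A @ c
                green[j] = ndimage.affine_transform(green[j], A, offset=off, order=1)
                red[j] = ndimage.affine_transform(red[j], A, offset=off, order=1)
                vm = ndimage.affine_transform(
                    valid[j].astype(np.float32), A, offset=off, order=1, cval=0.0
                )
                valid[j] = vm > 0.999
                img = (green[j] + red[j]).astype(np.float64)
        sh, error, _ = phase_cross_correlation(
            ref_c, img[crop], upsample_factor=upsample, normalization=None
        )
        # error = 1 − normalized correlation peak²
        corr = float(np.sqrt(max(1.0 - error, 0.0)))
        if corr < min_correlation:
            sh = prev_shift.copy()
        else:
            prev_shift = np.asarray(sh, dtype=float)
        if np.any(np.abs(sh) > 1e-6):
            green[j] = ndimage.shift(green[j], sh, order=1)
            red[j] = ndimage.shift(red[j], sh, order=1)
            # conservative mask update: integer roll + guard border
            ir = int(np.ceil(abs(sh[0]))), int(np.ceil(abs(sh[1])))
            vm = np.roll(valid[j], (int(round(sh[0])), int(round(sh[1]))),
                         axis=(0, 1))
            if ir[0]:
                vm[: ir[0]] = False
                vm[-ir[0]:] = False
            if ir[1]:
                vm[:, : ir[1]] = False
                vm[:, -ir[1]:] = False
            valid[j] = vm
        shifts[j] += sh
        angle[j] += extra_rot
    return RegisteredStack(
        green=green, red=red, valid=valid, angle_applied=angle,
        center=reg.center, shifts=shifts,
        pixel_size_um=reg.pixel_size_um, frame_rate=reg.frame_rate,
        metadata=dict(reg.metadata), background=reg.background,
    )


def subtract_background(
    reg: RegisteredStack,
    region: np.ndarray | None = None,
) -> RegisteredStack:
    """Subtract the first-percentile intensity of a non-fluorescent region.

    Without an explicit region mask, the lowest decile of the temporal-mean
    intensity (inside the always-valid area) is used as the non-fluorescent
    region.  Each channel gets its own scalar; results are clipped at 0.
    """
    always = reg.valid.all(axis=0)
    mean_img = (reg.green.mean(axis=0, dtype=np.float32)
                + reg.red.mean(axis=0, dtype=np.float32)) / 2.0
    if region is None:
        if not always.any():
            raise ValueError("no always-valid pixels to estimate background from")
        thr = np.percentile(mean_img[always], 10)
        region = always & (mean_img <= thr)
    else:
        region = np.asarray(region, bool) & always
    if not region.any():
        raise ValueError("background region is empty")
    dark_ref = float(np.percentile(mean_img[always], 1))
    region_med = float(np.median(mean_img[region]))
    if region_med > 2.0 * max(dark_ref, 1e-9) + 1.0:
        warnings.warn(
            "background region is much brighter than the darkest pixels; "
            "it may cover fluorescent structures"
        )
    levels = []
    out = {}
    for name, ch in (("green", reg.green), ("red", reg.red)):
        val = float(np.percentile(ch[:, region], 1))
        sub = ch - np.float32(val)
        np.maximum(sub, 0, out=sub)
        out[name] = sub
        levels.append(val)
    return RegisteredStack(
        green=out["green"], red=out["red"], valid=reg.valid,
        angle_applied=reg.angle_applied, center=reg.center, shifts=reg.shifts,
        pixel_size_um=reg.pixel_size_um, frame_rate=reg.frame_rate,
        metadata=dict(reg.metadata), background=tuple(levels),
    )


# ---------------------------------------------------------------------------
# cross-sample alignment


@dataclass
class SampleMap:
    """A per-sample cell/vector table in its own anatomical frame.

    ``table`` columns use the _rc/_ml suffix convention for axis
    components; ``landmark_um`` is the lateral-edge landmark (x_rc, y_ml).
    """

    table: pd.DataFrame
    side: str
    landmark_um: tuple | None = None


def align_across_samples(maps: list[SampleMap]) -> list[pd.DataFrame]:
    """Mirror right-side maps and translate all maps to a shared origin.

    Right-ear maps are mirrored about the rostro-caudal axis (every *_ml
    column negated), then each table is translated so its lateral-edge
    landmark sits at the origin of the common frame.
    """
    out = []
    for m in maps:
        if m.landmark_um is None:
            raise ValueError("every map needs a lateral-edge landmark")
        df = m.table.copy()
        lx, ly = float(m.landmark_um[0]), float(m.landmark_um[1])
        if m.side == "right":
            for col in df.columns:
                if col.endswith("_ml"):
                    df[col] = -df[col]
            ly = -ly
        elif m.side != "left":
            raise ValueError("side must be 'left' or 'right'")
        if "x_rc" in df.columns:
            df["x_rc"] = df["x_rc"] - lx
        if "y_ml" in df.columns:
            df["y_ml"] = df["y_ml"] - ly
        out.append(df)
    return out
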