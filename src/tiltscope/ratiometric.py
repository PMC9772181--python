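"""Green/red ratio, baselines and ΔR/R0 quantification.

ΔR/R0 is the fractional change of the green-to-red fluorescence ratio from
its pre-stimulus baseline.  Because the dominant optical artifact of the
rotating light path is multiplicative and common to both channels, the
ratio cancels it: a gain swing of ±50% in single-channel intensity leaves
ΔR/R0 within a few percent.

Pixelwise processing: per-frame 3×3 median filter on each channel, then
R = green/red, R0 = mean ratio over the pre-motion baseline window, and
ΔR/R0 = R/R0 − 1 wherever the red denominator is trustworthy.

ROI processing: per-ROI channel means → ratio → R0 → ΔR/R0 smoothed by a
centered 3-frame boxcar (edges truncated).  Bead ROIs are 1.5 µm discs.
Bleaching/photoconversion trends can be removed per channel by fitting
straight lines to the quiet windows before the first and after the last
stage motion and interpolating the trend linearly in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .registration import RegisteredStack

__all__ = [
    "RatioStack",
    "RoiTraceSet",
    "ratio_stack",
    "roi_traces",
    "detrend_photoconversion",
    "boxcar_smooth",
    "disc_rois",
]


def boxcar_smooth(x: np.ndarray, window: int = 3, axis: int = -1) -> np.ndarray:
    """Centered moving average with truncated (renormalized) edges."""
    if window <= 1:
        return np.asarray(x, dtype=float).copy()
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    kernel = np.ones(window)
    num = np.apply_along_axis(lambda v: np.convolve(v, kernel, "same"), -1, x)
    cnt = np.convolve(np.ones(x.shape[-1]), kernel, "same")
    return np.moveaxis(num / cnt, -1, axis)


@dataclass
class RatioStack:
    """Pixelwise ratio stack: R(t), baseline R0, ΔR/R0 frames and validity."""

    ratio: np.ndarray    # (T, H, W)
    baseline: np.ndarray  # (H, W)
    drr: np.ndarray      # (T, H, W) fractional ΔR/R0
    valid: np.ndarray    # (T, H, W) bool
    frame_rate: float


def ratio_stack(
    reg: RegisteredStack,
    baseline_window,
    *,
    median_size: int = 3,
    red_floor_frac: float = 0.05,
) -> RatioStack:
    """Pixelwise ΔR/R0 from a registered stack.

    ``baseline_window`` indexes the pre-motion frames (slice or frame
    indices).  Pixels whose red intensity falls below ``red_floor_frac`` of
    the red median, or whose baseline is undefined, are masked rather than
    producing unstable ratios.
    """
    bidx = np.arange(reg.n_frames)[baseline_window]
    if len(bidx) == 0:
        raise ValueError("baseline window is empty")
    g = np.empty_like(reg.green, dtype=np.float32)
    r = np.empty_like(reg.red, dtype=np.float32)
    for j in range(reg.n_frames):
        g[j] = ndimage.median_filter(reg.green[j], size=median_size)
        r[j] = ndimage.median_filter(reg.red[j], size=median_size)
    red_med = np.median(r[r > 0]) if np.any(r > 0) else 0.0
    floor = red_floor_frac * red_med
    valid = reg.valid & (r > floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, g / np.maximum(r, 1e-12), np.nan)
    base_valid = valid[bidx].all(axis=0)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        baseline = np.where(base_valid, np.nanmean(ratio[bidx], axis=0), np.nan)
    ok = base_valid & (baseline > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        drr = np.where(valid & ok[None], ratio / baseline[None] - 1.0, np.nan)
    return RatioStack(ratio=ratio, baseline=baseline, drr=drr,
                      valid=valid & ok[None], frame_rate=reg.frame_rate)


def disc_rois(centers, radius_um: float, shape, pixel_size_um: float):
    """Disc ROI masks from (row, col) centers and a physical radius."""
    r_px = radius_um / pixel_size_um
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    masks = []
    for (cr, cc) in np.atleast_2d(centers):
        masks.append((yy - cr) ** 2 + (xx - cc) ** 2 <= r_px**2)
    return masks


@dataclass
class RoiTraceSet:
    """Per-ROI green/red/ratio/ΔR/R0 time series.

    ``drr`` rows are fractional ΔR/R0 computed from the boxcar-smoothed
    ratio; ``flagged`` marks frames where an ROI left the valid area.
    """

    roi_ids: np.ndarray
    t: np.ndarray
    green: np.ndarray   # (n, T) mean intensities
    red: np.ndarray
    ratio: np.ndarray
    r0: np.ndarray      # (n,)
    drr: np.ndarray     # (n, T)
    flagged: np.ndarray  # (n, T) bool
    smoothing_window: int = 3
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.roi_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rid in enumerate(self.roi_ids):
            rows.append(pd.DataFrame({
                "roi_id": rid, "t_s": self.t,
                "green": self.green[i], "red": self.red[i],
                "ratio": self.ratio[i], "dRR": self.drr[i],
                "flagged": self.flagged[i],
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def roi_traces(
    reg: RegisteredStack,
    rois,
    baseline_window,
    *,
    smoothing_window: int = 3,
    detrend: tuple | None = None,
    roi_ids=None,
) -> RoiTraceSet:
    """Measure per-ROI channel means and derive smoothed ΔR/R0 traces.

    ``rois`` is a list of boolean masks (one per ROI).  ``detrend``, if
    given, is a (pre_window, post_window) pair of frame indexers bracketing
    all stage motion; linear bleaching trends are then removed per channel
    before the ratio is formed.  R0 is the mean pre-motion ratio.
    """
    T = reg.n_frames
    t = np.arange(T) / reg.frame_rate
    n = len(rois)
    green = np.empty((n, T))
    red = np.empty((n, T))
    flagged = np.zeros((n, T), bool)
    for i, mask in enumerate(rois):
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError(f"ROI {i} is empty")
        area = mask.sum()
        gsum = reg.green[:, mask]
        rsum = reg.red[:, mask]
        vsum = reg.valid[:, mask]
        inside = vsum.all(axis=1)
        flagged[i] = ~inside
        green[i] = gsum.mean(axis=1)
        red[i] = rsum.mean(axis=1)
        # where partially invalid, average only valid pixels
        part = ~inside & vsum.any(axis=1)
        if part.any():
            w = vsum[part]
            green[i, part] = (gsum[part] * w).sum(1) / w.sum(1)
            red[i, part] = (rsum[part] * w).sum(1) / w.sum(1)

    if detrend is not None:
        pre, post = detrend
        for arr in (green, red):
            for i in range(n):
                arr[i] = detrend_photoconversion(arr[i], t, pre, post)

    bidx = np.arange(T)[baseline_window]
    if len(bidx) == 0:
        raise ValueError("baseline window is empty")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = green / np.maximum(red, 1e-12)
    r0 = ratio[:, bidx].mean(axis=1)
    if np.any(r0 <= 0):
        raise ValueError("nonpositive baseline ratio; check ROIs and background")
    smooth = boxcar_smooth(ratio, smoothing_window, axis=1)
    drr = smooth / r0[:, None] - 1.0
    ids = np.asarray(roi_ids) if roi_ids is not None else np.arange(n)
    return RoiTraceSet(roi_ids=ids, t=t, green=green, red=red, ratio=ratio,
                       r0=r0, drr=drr, flagged=flagged,
                       smoothing_window=smoothing_window)


def detrend_photoconversion(signal, t, pre_window, post_window) -> np.ndarray:
    """Remove a linear bleaching/photoconversion trend from one channel.

    Straight lines are fit to the quiet windows before the first and after
    the last stage motion; between the windows the trend interpolates
    linearly between the pre-fit value at the end of the pre window and the
    post-fit value at the start of the post window.  The trend minus its
    initial value is subtracted, so the signal keeps its starting level.
    """
    signal = np.asarray(signal, dtype=float)
    t = np.asarray(t, dtype=float)
    pre_idx = np.arange(len(t))[pre_window]
    post_idx = np.arange(len(t))[post_window]
    if len(pre_idx) < 5 or len(post_idx) < 5:
        raise ValueError("quiet windows must contain at least 5 samples each")
    cp = np.polyfit(t[pre_idx], signal[pre_idx], 1)
    cq = np.polyfit(t[post_idx], signal[post_idx], 1)
    trend = np.empty_like(signal)
    trend[pre_idx[0]:pre_idx[-1] + 1] = np.polyval(cp, t[pre_idx[0]:pre_idx[-1] + 1])
    trend[post_idx[0]:post_idx[-1] + 1] = np.polyval(
        cq, t[post_idx[0]:post_idx[-1] + 1]
    )
    trend[:pre_idx[0]] = np.polyval(cp, t[:pre_idx[0]])
    trend[post_idx[-1] + 1:] = np.polyval(cq, t[post_idx[-1] + 1:])
    a, b = pre_idx[-1], post_idx[0]
    if b > a + 1:
        va, vb = np.polyval(cp, t[a]), np.polyval(cq, t[b])
        trend[a + 1:b] = np.interp(t[a + 1:b], [t[a], t[b]], [va, vb])
    return signal - (trend - trend[pre_idx[0]])
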