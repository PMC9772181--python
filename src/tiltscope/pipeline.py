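"""End-to-end orchestration: synthesize → register → ratio → respond → compare.

A :class:`RunConfig` fully determines a run; the same config and seed give
identical CSV outputs.  One utricle is imaged end-to-end (rendered rotating
stacks, bead-based registration, ROI ΔR/R0 measurement); additional
utricles for the pooled vector-field and striola statistics are simulated
at trace level under the same response model and measured with the same
amplitude windows, which keeps a full demo run on one CPU in minutes.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import registration as reg_mod
from . import responses as resp_mod
from . import striola as striola_mod
from .ratiometric import disc_rois, roi_traces, boxcar_smooth
from .stimulus import StageTrajectory, make_tilt_trajectory, make_vibration_trajectory
from .synthetic import (
    Acquisition,
    ArtifactModel,
    MaculaLayout,
    ResponseModel,
    bead_sources,
    layout_sources,
    make_bead_field,
    make_macula_layout,
    render_stack,
    simulate_responses,
)

log = logging.getLogger("tiltscope")

__all__ = ["RunConfig", "demo_config", "run_pipeline", "make_report",
           "stage_seed", "register_stack", "measure_stack",
           "session_amplitudes_from_traces"]


def stage_seed(seed: int, name: str) -> int:
    """Counter-based per-stage seed fan-out (stable across runs)."""
    return int(np.random.SeedSequence([seed, zlib.crc32(name.encode())])
               .generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Fully resolved configuration of a pipeline run."""

    seed: int = 0
    outdir: str = "tiltscope_run"
    n_utricles: int = 6
    n_rendered: int = 1
    n_cells: int = 85
    semi_axes_um: tuple = (55.0, 30.0)
    fov: tuple = (448, 456)
    n_beads: int = 40
    radius_m: float = 0.1
    tilt_threshold: float = 10.0
    vibration_threshold: float = 5.0
    biphasic_threshold: float = -5.0
    sample_rate: float = 1000.0
    frame_rate: float = 10.0
    response_model: dict = field(default_factory=dict)
    artifact: dict = field(default_factory=dict)

    _KNOWN = None

    def __post_init__(self):
        known = set(ResponseModel.__dataclass_fields__)
        bad = set(self.response_model) - known
        if bad:
            raise ValueError(f"invalid response_model keys: {sorted(bad)}")
        known_a = set(ArtifactModel.__dataclass_fields__)
        bad = set(self.artifact) - known_a
        if bad:
            raise ValueError(f"invalid artifact keys: {sorted(bad)}")

    def model(self) -> ResponseModel:
        return ResponseModel(**self.response_model)

    def artifact_model(self) -> ArtifactModel:
        return ArtifactModel(**self.artifact)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def demo_config(seed: int = 0, outdir: str = "tiltscope_demo") -> RunConfig:
    """A reduced-scale configuration that runs end to end in minutes:
    a smaller macula and field of view, one rendered utricle plus two
    trace-level utricles for the pooled statistics."""
    return RunConfig(seed=seed, outdir=outdir, n_utricles=3, n_rendered=1,
                     n_cells=40, semi_axes_um=(30.0, 18.0), fov=(256, 256),
                     n_beads=25)


# ---------------------------------------------------------------------------
# reusable stage helpers


def register_stack(stack, rotation_estimate=None, refine: bool = True,
                   repair: bool = True):
    """Bead-style registration chain for one stack.

    Hot pixels are repaired first (they smear into arcs once the rotation
    is corrected).  If no rotation estimate is supplied (no bead
    recording), it is estimated directly from the stack's own bright
    sources.
    """
    if repair and stack.n_frames >= 3:
        stack, _ = reg_mod.repair_hot_pixels(stack)
    est = rotation_estimate or reg_mod.estimate_rotation(stack)
    reg = reg_mod.derotate_stack(stack, est)
    if refine:
        reg = reg_mod.refine_registration(reg)
    return reg_mod.subtract_background(reg), est


def measure_stack(reg, centers_px, radius_um, traj, *, detrend: bool = False):
    """Disc-ROI ΔR/R0 traces with the protocol's pre-motion baseline."""
    t = np.arange(reg.n_frames) / reg.frame_rate
    first = traj.first_motion_time()
    baseline = t < first - 1e-9
    masks = disc_rois(centers_px, radius_um, reg.green.shape[1:],
                      reg.pixel_size_um)
    dt = None
    if detrend:
        last = traj.last_motion_time()
        dt = (t < first - 1e-9, t > last + 1e-9)
    return roi_traces(reg, masks, baseline, detrend=dt)


def session_amplitudes_from_traces(traces: np.ndarray, t: np.ndarray,
                                   traj: StageTrajectory, *,
                                   cell_kind: str = "hc",
                                   smooth: int = 3) -> np.ndarray:
    """(+, −) tilt amplitudes per cell from fractional ΔR/R0 traces."""
    sm = boxcar_smooth(traces, smooth, axis=1)
    out = np.empty((len(sm), 2))
    for i in range(len(sm)):
        if cell_kind == "hc":
            out[i] = resp_mod.tilt_amplitude_hc(sm[i], t, traj)
        else:
            out[i] = resp_mod.tilt_amplitude_vgn(sm[i], t, traj)[0]
    return out


def _truth_cell_table(layout: MaculaLayout, model: ResponseModel,
                      traj_tilt, traj_vib, seed: int,
                      radius_m: float, frame_rate: float,
                      utricle_id: int) -> pd.DataFrame:
    """Per-cell amplitudes/vectors from noise-free truth traces."""
    amps = {}
    vib = {}
    for session in ("pitch", "roll"):
        tr = simulate_responses(layout, traj_tilt, model, session=session,
                                radius_m=radius_m, frame_rate=frame_rate,
                                seed=stage_seed(seed, f"resp-{utricle_id}"))
        amps[session] = session_amplitudes_from_traces(tr.traces, tr.t, traj_tilt)
        trv = simulate_responses(layout, traj_vib, model, session=session,
                                 radius_m=radius_m, frame_rate=frame_rate,
                                 seed=stage_seed(seed, f"resp-{utricle_id}"))
        sm = boxcar_smooth(trv.traces, 3, axis=1)
        vib[session] = np.array([
            resp_mod.vibration_amplitude(sm[i], trv.t, traj_vib)
            for i in range(layout.n)
        ])
    return _cell_table_from_amps(layout, amps, vib, utricle_id)


def _cell_table_from_amps(layout: MaculaLayout, amps: dict, vib: dict,
                          utricle_id: int) -> pd.DataFrame:
    rows = []
    for i in range(layout.n):
        nd, td = amps["pitch"][i]
        ld, md = amps["roll"][i]
        pref, anti, length = resp_mod.response_vector((nd, td), (ld, md))
        vp, vr = vib["pitch"][i], vib["roll"][i]
        bars, vlen = resp_mod.vibration_vector(vp, vr)
        dp, _, _ = resp_mod.classify_direction_hc(nd, td, ("nose_down", "tail_down"))
        dr, _, _ = resp_mod.classify_direction_hc(ld, md,
                                                  ("lateral_down", "medial_down"))
        a = {"nose_down": nd, "tail_down": td, "lateral_down": ld,
             "medial_down": md}
        cand = [d for d in (dp, dr) if d is not None]
        direction = max(cand, key=lambda d: a[d]) if cand else "none"
        rows.append(dict(
            utricle_id=utricle_id, cell_id=int(layout.cells.cell_id.iloc[i]),
            x_rc=float(layout.cells.x_rc.iloc[i]),
            y_ml=float(layout.cells.y_ml.iloc[i]),
            striolar=bool(layout.cells.striolar.iloc[i]),
            nose_down=nd, tail_down=td, lateral_down=ld, medial_down=md,
            tilt_activated=resp_mod.classify_activation([nd, td, ld, md], "tilt"),
            tilt_direction=direction,
            pref_rc=pref[0], pref_ml=pref[1], anti_rc=anti[0], anti_ml=anti[1],
            length=length,
            vib_pitch=vp, vib_roll=vr, vib_length=vlen,
            vib_activated=resp_mod.classify_activation([vp, vr], "vibration"),
        ))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write CSV outputs + resolved config.

    Returns a result bundle dict with the per-stage products.  Stage
    failures raise with the stage name; everything produced before the
    failure remains on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.json")
    bundle: dict = {"config": config}
    t0 = time.time()

    def stage(name):
        log.info("stage %-10s +%5.1fs", name, time.time() - t0)

    # --- synthesize -------------------------------------------------------
    stage("synth")
    traj_tilt = make_tilt_trajectory("tilt90", sample_rate=config.sample_rate)
    traj_vib = make_vibration_trajectory(sample_rate=config.sample_rate)
    traj_tilt.to_csv(out / "trajectory_tilt90.csv")
    traj_vib.to_csv(out / "trajectory_vibration.csv")
    model = config.model()
    artifact = config.artifact_model()
    acq = Acquisition(fov=tuple(config.fov), frame_rate=config.frame_rate)

    layouts = [
        make_macula_layout(config.n_cells,
                           seed=stage_seed(config.seed, f"layout-{u}"),
                           semi_axes_um=tuple(config.semi_axes_um))
        for u in range(config.n_utricles)
    ]

    # --- image + register + measure the rendered utricle(s) ---------------
    tables = []
    for u, layout in enumerate(layouts):
        if u < config.n_rendered:
            stage(f"render-u{u}")
            tables.append(_imaged_cell_table(layout, model, artifact, acq,
                                             traj_tilt, traj_vib, config, u,
                                             out))
        else:
            tables.append(_truth_cell_table(layout, model, traj_tilt, traj_vib,
                                            config.seed, config.radius_m,
                                            config.frame_rate, u))
    cells = pd.concat(tables, ignore_index=True)
    cells.to_csv(out / "cells.csv", index=False, float_format="%.6g")
    bundle["cells"] = cells

    # --- pooled grids -----------------------------------------------------
    stage("grid")
    maps = [
        reg_mod.SampleMap(
            table=t, side="left",
            landmark_um=(0.0, float(np.max(t.y_ml))),
        )
        for t in tables
    ]
    aligned = pd.concat(reg_mod.align_across_samples(maps), ignore_index=True)
    grid = resp_mod.build_grid(aligned[["x_rc", "y_ml"]].to_numpy(),
                               aligned.utricle_id.to_numpy())
    tilt_grid = resp_mod.grid_mean_vectors(
        aligned[["x_rc", "y_ml"]].to_numpy(),
        aligned[["pref_rc", "pref_ml"]].to_numpy(), grid)
    _grid_csv(tilt_grid, out / "grid_tilt.csv")
    bundle["grid_tilt"] = tilt_grid
    bundle["aligned"] = aligned

    # --- striola statistics ----------------------------------------------
    stage("compare")
    groups_tilt, _ = striola_mod.polarity_groups(aligned, length_col="length")
    groups_tilt = striola_mod.exclude_striola_only(groups_tilt)
    res_tilt, pairs_tilt = striola_mod.compare_striola_extrastriola(
        groups_tilt, "tilt")
    groups_vib, _ = striola_mod.polarity_groups(aligned, length_col="vib_length")
    groups_vib = striola_mod.exclude_striola_only(groups_vib)
    res_vib, pairs_vib = striola_mod.compare_striola_extrastriola(
        groups_vib, "vibration")
    pd.concat([pairs_tilt, pairs_vib]).to_csv(
        out / "striola_pairs.csv", index=False, float_format="%.6g")
    pd.DataFrame([
        dict(modality="tilt", **asdict(res_tilt)),
        dict(modality="vibration", **asdict(res_vib)),
    ]).to_csv(out / "striola_tests.csv", index=False, float_format="%.6g")
    bundle["striola"] = {"tilt": res_tilt, "vibration": res_vib}
    stage("done")
    return bundle


def _imaged_cell_table(layout, model, artifact, acq, traj_tilt, traj_vib,
                       config: RunConfig, u: int, out: Path) -> pd.DataFrame:
    """Full imaging chain for one utricle: beads → stacks → registration →
    ΔR/R0 → amplitudes."""
    beads = make_bead_field(config.n_beads, fov=tuple(config.fov),
                            seed=stage_seed(config.seed, f"beads-{u}"))
    amps, vib = {}, {}
    for session in ("pitch", "roll"):
        src = layout_sources(layout, acq, session=session)
        # bead reference recording with the same stimulus, reused for the fish
        bead_stack = render_stack(
            bead_sources(beads), traj_tilt, artifact=artifact, acq=acq,
            seed=stage_seed(config.seed, f"beadstack-{u}-{session}"))
        est = reg_mod.estimate_rotation(bead_stack)
        del bead_stack

        tr = simulate_responses(layout, traj_tilt, model, session=session,
                                radius_m=config.radius_m,
                                frame_rate=config.frame_rate,
                                seed=stage_seed(config.seed, f"resp-{u}"))
        stack = render_stack(src, traj_tilt, traces=tr, artifact=artifact,
                             acq=acq,
                             seed=stage_seed(config.seed, f"stack-{u}-{session}"))
        reg, _ = register_stack(stack, rotation_estimate=est)
        del stack
        traces = measure_stack(
            reg, src[["row_off", "col_off"]].to_numpy() + acq.center(),
            float(layout.cells.soma_radius_um.iloc[0]), traj_tilt)
        del reg
        amps[session] = np.column_stack(
            [resp_mod.tilt_amplitude_hc(traces.drr[i], traces.t, traj_tilt)
             for i in range(traces.n)]).T

        trv = simulate_responses(layout, traj_vib, model, session=session,
                                 radius_m=config.radius_m,
                                 frame_rate=config.frame_rate,
                                 seed=stage_seed(config.seed, f"resp-{u}"))
        vstack = render_stack(src, traj_vib, traces=trv, artifact=artifact,
                              acq=acq,
                              seed=stage_seed(config.seed, f"vstack-{u}-{session}"))
        vreg, _ = register_stack(vstack)
        del vstack
        vtraces = measure_stack(
            vreg, src[["row_off", "col_off"]].to_numpy() + acq.center(),
            float(layout.cells.soma_radius_um.iloc[0]), traj_vib)
        del vreg
        vib[session] = np.array([
            resp_mod.vibration_amplitude(vtraces.drr[i], vtraces.t, traj_vib)
            for i in range(vtraces.n)
        ])
    return _cell_table_from_amps(layout, amps, vib, u)


def _grid_csv(grid: resp_mod.GridSummary, path) -> None:
    m = grid.nonempty()
    pd.DataFrame({
        "x_rc": grid.points[m, 0], "y_ml": grid.points[m, 1],
        "mean_rc": grid.mean_vectors[m, 0], "mean_ml": grid.mean_vectors[m, 1],
        "n_cells": grid.counts[m],
    }).to_csv(path, index=False, float_format="%.6g")


def make_report(bundle: dict, path=None):
    """Summary figures: direction map, vector field, polar histogram,
    paired striola scatter.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = bundle["aligned"] if "aligned" in bundle else bundle["cells"]
    fig, axes = plt.subplots(2, 2, figsize=(10, 9))

    ax = axes[0, 0]
    act = cells[cells.tilt_activated]
    ax.quiver(act.x_rc, act.y_ml, act.pref_rc, act.pref_ml,
              color="m", angles="xy", width=0.004)
    ax.set_title(f"tilt response vectors ({len(act)} activated cells)")
    ax.set_xlabel("rostro-caudal (µm)")
    ax.set_ylabel("medio-lateral (µm)")
    ax.set_aspect("equal")

    ax = axes[0, 1]
    grid = bundle.get("grid_tilt")
    if grid is not None and grid.nonempty().any():
        m = grid.nonempty()
        ax.quiver(grid.points[m, 0], grid.points[m, 1],
                  grid.mean_vectors[m, 0], grid.mean_vectors[m, 1],
                  color="k", angles="xy", width=0.004)
        ax.set_title(f"grid-mean vectors ({m.sum()} points, "
                     f"interval {grid.interval:.1f} µm)")
    ax.set_aspect("equal")

    ax = axes[1, 0]
    norm = np.hypot(cells.pref_rc, cells.pref_ml)
    ang = np.radians(np.degrees(np.arctan2(cells.pref_ml[norm > 0],
                                           cells.pref_rc[norm > 0])) % 360)
    counts, edges = np.histogram(ang, bins=36, range=(0, 2 * np.pi))
    ax.remove()
    ax = fig.add_subplot(2, 2, 3, projection="polar")
    ax.bar((edges[:-1] + edges[1:]) / 2, counts, width=np.diff(edges),
           color="m", alpha=0.6)
    ax.set_title(f"polarity histogram (n={counts.sum()})")

    ax = axes[1, 1]
    st = bundle.get("striola")
    if st is not None:
        res = st["tilt"]
        ax.set_title(
            f"striola vs extrastriola: tilt p={res.p_two_sided:.2g} "
            f"({res.direction}, n={res.n_pairs})")
    vib_act = int(cells.vib_activated.sum()) if "vib_activated" in cells else 0
    ax.text(0.05, 0.8, f"vibration-activated cells: {vib_act}",
            transform=ax.transAxes)
    ax.text(0.05, 0.6, f"tilt-activated cells: {int(cells.tilt_activated.sum())}",
            transform=ax.transAxes)
    ax.axis("off")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
    return fig
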