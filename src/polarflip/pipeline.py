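"""End-to-end pipeline runner: dataset in, tables and kymographs out.

Stages per cell: camera correction -> per-frame segmentation -> (optional)
ratio correction -> track linking and kinematics -> front/rear/middle region
traces -> event detection -> response classification -> length-normalized 1D
profiles. Cohort stages: kymograph assembly and class-count summary. Cell
failures are isolated: a malformed or unsegmentable cell is logged on the
manifest and the rest of the cohort proceeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .correction import CorrectionSet, apply_camera_corrections, apply_ratio_correction
from .events import (
    RegionActivitySeries,
    classify_persistent,
    classify_transient,
    detect_events,
)
from .io import list_cell_dirs, read_cell_dir, read_meta
from .profiles import build_kymograph, fret_profile_1d, normalize_profile, profile_1d
from .regions import edge_regions, normalized_region_signal, region_activity
from .segmentation import NoCellError, compute_ratio_image, segment_frame
from .tracking import (
    CellTrack,
    compute_kinematics,
    link_track,
    signed_axial_velocity,
)

log = logging.getLogger("polarflip")


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to reproduce it bit-exactly."""

    dataset_dir: str
    config: dict
    config_hash: str
    n_cells: int = 0
    cell_status: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CellResult:
    cell_id: str
    track: CellTrack
    series: RegionActivitySeries
    signed_velocity: np.ndarray
    events: object
    label: object
    profiles: list  # (offsets, values) per observation, rear -> front
    original_sign: int
    mode: str


def analyze_cell(
    cell_dir: str | Path,
    config: Optional[AnalysisConfig] = None,
    correction: Optional[np.ndarray] = None,
) -> CellResult:
    """Run all single-cell stages for one cell directory."""
    config = config or AnalysisConfig()
    cell_dir = Path(cell_dir)
    stack = read_cell_dir(cell_dir)
    meta = read_meta(cell_dir)
    corr = CorrectionSet.flat(stack.acq.field_shape, dark=stack.acq.dark_offset)

    masks: list[Optional[np.ndarray]] = []
    donor_frames = []
    acceptor_frames = []
    for k in range(stack.n_frames):
        d = apply_camera_corrections(stack.channel_a[k], corr)
        a = apply_camera_corrections(stack.channel_b[k], corr)
        try:
            seg = segment_frame(d, a, min_size=config.min_object_px)
            masks.append(seg.mask)
            donor_frames.append(seg.donor_bgsub)
            acceptor_frames.append(seg.acceptor_bgsub)
        except NoCellError:
            log.warning("%s: no cell in frame %d, skipped", cell_dir.name, k)
            masks.append(None)
            donor_frames.append(None)
            acceptor_frames.append(None)

    track = link_track(masks)
    track = compute_kinematics(
        track,
        stack.acq.frame_interval_s,
        stack.acq.pixel_size_um,
        reference_frame=stack.stim_frame if any(
            o.frame_index == stack.stim_frame for o in track.observations
        ) else None,
        span=config.loess_span,
    )

    # Original (pre-stimulus) movement direction along the channel axis.
    rows = track.centroids()[:, 0]
    pre = track.frame_indices() <= stack.stim_frame
    steps = np.sign(np.diff(rows[pre])) if pre.sum() >= 2 else np.sign(np.diff(rows))
    original_sign = int(np.sign(steps.sum())) or -1
    direction = (original_sign, 0.0)

    times, fronts, rears, middles, wholes = [], [], [], [], []
    profiles = []
    for o in track.observations:
        k = o.frame_index
        d = donor_frames[k]
        a = acceptor_frames[k]
        dm = np.where(o.mask, d, np.nan)
        am = np.where(o.mask, a, np.nan)
        regions = edge_regions(o.mask, direction, config.region_size_px)
        if stack.mode == "fret":
            if correction is not None:
                # fold the ratio correction into the acceptor channel so that
                # every downstream ratio-of-sums carries it
                am = apply_ratio_correction(am, correction)
            vals = region_activity(dm, am, regions, cell_mask=o.mask)
            offs, prof = fret_profile_1d(dm, am, o.mask)
        else:
            # channel_a is the myosin reporter in myosin mode
            vals = normalized_region_signal(dm, regions, o.mask)
            offs, prof = profile_1d(dm, o.mask)
        times.append((k - stack.stim_frame) * stack.acq.frame_interval_s)
        fronts.append(vals["front"])
        rears.append(vals["rear"])
        middles.append(vals["middle"])
        wholes.append(vals["whole"])
        if original_sign < 0:
            # moving up: the rear is the high-row end; flip to rear -> front
            prof = prof[::-1]
        profiles.append((offs, prof))

    series = RegionActivitySeries(
        time_s=np.array(times),
        front=np.array(fronts),
        rear=np.array(rears),
        middle=np.array(middles),
        whole=np.array(wholes),
        mode=stack.mode,
    )
    vel = signed_axial_velocity(
        track,
        stack.acq.frame_interval_s,
        stack.acq.pixel_size_um,
        reference_sign=original_sign,
    )
    events = detect_events(series.front, series.rear, vel, series.time_s, config)
    stim_mode = meta.get("stim_mode", "transient")
    if stim_mode == "persistent":
        label = classify_persistent(series, vel, config)
    else:
        label = classify_transient(series, vel, events, config)
    return CellResult(
        cell_id=cell_dir.name,
        track=track,
        series=series,
        signed_velocity=vel,
        events=events,
        label=label,
        profiles=profiles,
        original_sign=original_sign,
        mode=stack.mode,
    )


def _track_frame(res: CellResult, frame_interval_s: float) -> pd.DataFrame:
    tr = res.track
    frames = tr.frame_indices()
    cents = tr.centroids()
    return pd.DataFrame(
        {
            "cell_id": res.cell_id,
            "frame": frames,
            "time_s": res.series.time_s,
            "centroid_row": cents[:, 0],
            "centroid_col": cents[:, 1],
            "speed_um_s": tr.speed_um_s,
            "speed_smoothed_um_s": tr.speed_smoothed,
            "signed_velocity_um_s": res.signed_velocity,
            "area_px": tr.areas(),
            "major_axis_px": tr.major_axes(),
            "rel_length": tr.rel_length,
            "rel_area": tr.rel_area,
        }
    )


def _regions_frame(res: CellResult) -> pd.DataFrame:
    s = res.series
    return pd.DataFrame(
        {
            "cell_id": res.cell_id,
            "time_s": s.time_s,
            "front": s.front,
            "rear": s.rear,
            "middle": s.middle,
            "whole": s.whole,
            "mode": s.mode,
        }
    )


def run_pipeline(
    dataset_dir: str | Path,
    config: Optional[AnalysisConfig] = None,
    out_dir: str | Path = "polarflip_out",
    correction: Optional[np.ndarray] = None,
) -> Path:
    """Analyze every cell of a dataset and write cohort outputs.

    Writes ``tracks.csv``, ``region_traces.csv``, ``events.csv``,
    ``labels.csv``, ``kymograph.csv`` (+ ``kymograph_counts.csv``) and
    ``manifest.json`` under ``out_dir``. Per-cell failures are recorded in
    the manifest and do not abort the run; the exit contract is an exception
    only when *no* cell can be analyzed.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = list_cell_dirs(dataset_dir)
    manifest = RunManifest(
        dataset_dir=str(dataset_dir),
        config=asdict(config),
        config_hash=config_hash(config),
        n_cells=len(cells),
    )

    results: list[CellResult] = []
    for cd in cells:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = analyze_cell(cd, config, correction)
            results.append(res)
            manifest.cell_status[cd.name] = {
                "status": "ok",
                "n_frames": len(res.track),
                "skipped_frames": res.track.skipped_frames,
            }
        except Exception as e:  # noqa: BLE001 - isolation contract
            log.error("cell %s failed: %s", cd.name, e)
            manifest.cell_status[cd.name] = {"status": "error", "error": str(e)}
    if not results:
        raise RuntimeError("no cell could be analyzed")

    pd.concat(
        [_track_frame(r, config.frame_interval_s) for r in results]
    ).to_csv(out / "tracks.csv", index=False)
    pd.concat([_regions_frame(r) for r in results]).to_csv(
        out / "region_traces.csv", index=False
    )
    ev_rows = []
    for r in results:
        e = r.events
        ev_rows.append(
            {
                "cell_id": r.cell_id,
                "t_rear_response_s": e.t_rear_response_s,
                "t_front_response_s": e.t_front_response_s,
                "t_stall_s": e.t_stall_s,
                "t_crosspoint_s": e.t_crosspoint_s,
            }
        )
    pd.DataFrame(ev_rows).to_csv(out / "events.csv", index=False)
    lab_rows = []
    for r in results:
        row = {
            "cell_id": r.cell_id,
            "transient_class": r.label.transient_class,
            "persistent_class": r.label.persistent_class,
        }
        row.update({f"evidence_{k}": v for k, v in r.label.evidence.items()})
        lab_rows.append(row)
    pd.DataFrame(lab_rows).to_csv(out / "labels.csv", index=False)

    # cohort kymograph on the common stimulation-aligned grid
    try:
        kymo = cohort_kymograph(results, config)
        pd.DataFrame(kymo.matrix).to_csv(out / "kymograph.csv", index=False)
        pd.DataFrame({"time_s": kymo.time_s, "n_cells": kymo.n_cells}).to_csv(
            out / "kymograph_counts.csv", index=False
        )
    except ValueError as e:
        log.warning("kymograph skipped: %s", e)

    (out / "manifest.json").write_text(manifest.to_json())
    return out


def cohort_kymograph(results: list[CellResult], config: AnalysisConfig):
    """Rear-registered, length-normalized cohort kymograph.

    The normalized length is the cohort mean of per-cell mean major-axis
    length, rounded; profiles are resampled with the configured smoothing
    spline. Cells contribute NaN rows at frames they skipped.
    """
    target_length = int(round(np.mean([r.track.major_axes().mean() for r in results])))
    t_all = np.unique(np.concatenate([r.series.time_s for r in results]))
    per_cell = []
    for r in results:
        arr = np.full((t_all.size, target_length), np.nan)
        for (offs, prof), tt in zip(r.profiles, r.series.time_s):
            if np.isfinite(prof).sum() < 4:
                continue
            col = int(np.searchsorted(t_all, tt))
            arr[col] = normalize_profile(
                prof, target_length, smoothing_p=config.smoothing_p
            )
        per_cell.append(arr)
    return build_kymograph(per_cell, time_s=t_all)
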