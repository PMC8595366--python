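"""Dataset layout: one directory per cell with per-channel TIFFs + JSON sidecar.

A cell directory contains ``donor.tif``/``acceptor.tif`` (FRET mode) or
``myosin.tif``/``cyto.tif`` (myosin mode) as multi-page float TIFF stacks,
and ``meta.json`` with acquisition parameters and the stimulation log. This
mirrors the one-cell-per-channel acquisition of the assay.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import AcquisitionParams, FrameStack


def read_cell_dir(cell_dir: str | Path) -> FrameStack:
    """Load one cell's two-channel stack and sidecar metadata."""
    cell_dir = Path(cell_dir)
    meta_path = cell_dir / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed sidecar {meta_path}: {e}") from e
    mode = meta.get("mode", "fret")
    names = ("donor", "acceptor") if mode == "fret" else ("myosin", "cyto")
    stacks = []
    for name in names:
        path = cell_dir / f"{name}.tif"
        if not path.exists():
            raise FileNotFoundError(f"missing channel file {path}")
        stacks.append(np.asarray(tifffile.imread(path), dtype=float))
    if stacks[0].ndim == 2:
        stacks = [s[None] for s in stacks]
    acq = AcquisitionParams(
        frame_interval_s=meta.get("frame_interval_s", 3.0),
        pixel_size_um=meta.get("pixel_size_um", 0.21),
        field_shape=tuple(meta.get("field_shape", stacks[0].shape[1:])),
        dark_offset=meta.get("dark_offset", 0.0),
    )
    return FrameStack(
        channel_a=stacks[0],
        channel_b=stacks[1],
        acq=acq,
        stim_frame=int(meta.get("stim_frame", 0)),
        stim_targets=[tuple(x) for x in meta.get("stim_targets", [])],
        mode=mode,
    )


def read_meta(cell_dir: str | Path) -> dict:
    return json.loads((Path(cell_dir) / "meta.json").read_text())


def list_cell_dirs(dataset_dir: str | Path) -> list[Path]:
    """Cell directories of a dataset: subdirectories containing meta.json."""
    dataset_dir = Path(dataset_dir)
    cells = sorted(
        d for d in dataset_dir.iterdir() if d.is_dir() and (d / "meta.json").exists()
    )
    if not cells:
        raise FileNotFoundError(f"no cell directories under {dataset_dir}")
    return cells


def write_correction_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_mask_tiff(path: str | Path, masks: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(masks, dtype=bool) * 255).astype(np.uint8))
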