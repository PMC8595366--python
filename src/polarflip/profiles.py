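"""1D activity profiles, length-normalized resampling and kymographs.

Cell length varies across cells and time, so per-frame 1D profiles along the
channel axis are resampled onto a fixed number of points (the cohort-average
cell length) with a cubic smoothing spline before averaging. The smoothing
parameter follows the csaps convention: ``p = 0`` fits the least-squares
straight line, ``p = 1`` the interpolating cubic spline, with the default at
0.5. Kymographs stack the per-frame cohort-mean profiles into a
position-by-time matrix registered to the cell rear (rear at row 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline, make_smoothing_spline

DEFAULT_SMOOTHING_P = 0.5


def profile_1d(image: np.ndarray, mask: np.ndarray):
    """Per-row mean of a single-channel image over mask pixels.

    Returns ``(offsets, values)`` where offsets are row indices relative to
    the mask centroid row, covering the mask's row extent; rows of the extent
    with no mask pixels are NaN.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.nonzero(mask)[0]
    r0, r1 = rows.min(), rows.max()
    centroid_row = rows.mean()
    offsets = np.arange(r0, r1 + 1) - centroid_row
    values = np.full(offsets.size, np.nan)
    for i, r in enumerate(range(r0, r1 + 1)):
        sel = mask[r] & np.isfinite(image[r])
        if sel.any():
            values[i] = image[r][sel].mean()
    return offsets, values


def fret_profile_1d(donor: np.ndarray, acceptor: np.ndarray, mask: np.ndarray):
    """Per-row FRET activity profile: ratio of row sums inside the mask."""
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if donor.shape != mask.shape or acceptor.shape != mask.shape:
        raise ValueError("shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.nonzero(mask)[0]
    r0, r1 = rows.min(), rows.max()
    centroid_row = rows.mean()
    offsets = np.arange(r0, r1 + 1) - centroid_row
    values = np.full(offsets.size, np.nan)
    for i, r in enumerate(range(r0, r1 + 1)):
        sel = mask[r] & np.isfinite(donor[r]) & np.isfinite(acceptor[r])
        if sel.any():
            d = donor[r][sel].sum()
            if d > 0:
                values[i] = acceptor[r][sel].sum() / d
    return offsets, values


def normalize_profile(
    profile: np.ndarray,
    target_length: int,
    smoothing_p: float = DEFAULT_SMOOTHING_P,
    positions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Resample a 1D profile to ``target_length`` points with a smoothing spline.

    The profile is assumed oriented rear -> front; the output spans the same
    physical extent on ``target_length`` equally spaced points. ``smoothing_p``
    uses the csaps convention (0 = straight line, 1 = full interpolating fit);
    internally the penalized least-squares spline with ``lam = (1 - p) / p``
    realizes the same objective. NaN entries are dropped before fitting;
    at least 4 defined points are required.
    """
    profile = np.asarray(profile, dtype=float)
    if positions is None:
        positions = np.arange(profile.size, dtype=float)
    else:
        positions = np.asarray(positions, dtype=float)
    if not 0.0 <= smoothing_p <= 1.0:
        raise ValueError("smoothing_p must lie in [0, 1]")
    ok = np.isfinite(profile) & np.isfinite(positions)
    x, y = positions[ok], profile[ok]
    if x.size < 4:
        raise ValueError("profile must have at least 4 defined points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    xt = np.linspace(x[0], x[-1], int(target_length))
    if smoothing_p == 0.0:
        coef = np.polyfit(x, y, 1)
        return np.polyval(coef, xt)
    if smoothing_p == 1.0:
        spl = make_interp_spline(x, y, k=3)
        return spl(xt)
    lam = (1.0 - smoothing_p) / smoothing_p
    spl = make_smoothing_spline(x, y, lam=lam)
    return spl(xt)


@dataclass
class Kymograph:
    """Time-by-position cohort-average activity, rear-registered.

    ``matrix`` has shape (normalized length, n_frames) with the cell rear at
    row 0; ``n_cells[t]`` counts the cells contributing to column t.
    """

    matrix: np.ndarray
    n_cells: np.ndarray
    time_s: Optional[np.ndarray] = None


def build_kymograph(
    cell_profiles: Sequence[np.ndarray],
    time_s: Optional[np.ndarray] = None,
) -> Kymograph:
    """Average per-cell normalized profiles into a kymograph.

    ``cell_profiles`` holds one (n_frames, target_length) array per cell, all
    on a common stimulation-aligned time grid and a common normalized length,
    each profile running rear -> front. Cells may have NaN entries (e.g.
    skipped frames); they are excluded from the mean. A timepoint with no
    contributing cell raises.
    """
    if len(cell_profiles) == 0:
        raise ValueError("no cells")
    arr = np.stack([np.asarray(p, dtype=float) for p in cell_profiles])
    if arr.ndim != 3:
        raise ValueError("each cell profile must be a 2D (time, position) array")
    with np.errstate(all="ignore"):
        mean = np.nanmean(arr, axis=0)  # (T, L)
    has_data = np.isfinite(arr).any(axis=2)  # (cells, T)
    n_cells = has_data.sum(axis=0)
    if np.any(n_cells == 0):
        bad = int(np.flatnonzero(n_cells == 0)[0])
        raise ValueError(f"no cells contribute at timepoint {bad}")
    return Kymograph(matrix=mean.T, n_cells=n_cells, time_s=time_s)
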