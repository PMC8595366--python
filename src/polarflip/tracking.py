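"""Per-frame cell linking, kinematics, loess smoothing and rear targeting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.measure import regionprops


@dataclass
class CellObservation:
    """One segmented cell in one frame."""

    frame_index: int
    mask: np.ndarray
    centroid: tuple[float, float]  # (row, col)
    area_px: int
    major_axis_px: float
    movement_sign: int = 0  # +1 down-channel, -1 up-channel, 0 unknown

    @classmethod
    def from_mask(cls, frame_index: int, mask: np.ndarray) -> "CellObservation":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        props = regionprops(mask.astype(np.uint8))[0]
        return cls(
            frame_index=frame_index,
            mask=mask,
            centroid=(float(props.centroid[0]), float(props.centroid[1])),
            area_px=int(mask.sum()),
            major_axis_px=float(props.axis_major_length),
        )


@dataclass
class CellTrack:
    """A time-ordered single-cell track with derived kinematics.

    ``speed_um_s[k]`` is the centroid displacement between frames k-1 and k
    divided by the frame interval (NaN at k = 0 and across skipped frames);
    ``speed_smoothed`` is its loess-smoothed version. ``rel_length`` and
    ``rel_area`` are ratios to the value at the reference (pre-stimulus)
    frame.
    """

    observations: list[CellObservation]
    skipped_frames: list[int] = field(default_factory=list)
    speed_um_s: Optional[np.ndarray] = None
    speed_smoothed: Optional[np.ndarray] = None
    rel_length: Optional[np.ndarray] = None
    rel_area: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.observations)

    def frame_indices(self) -> np.ndarray:
        return np.array([o.frame_index for o in self.observations])

    def centroids(self) -> np.ndarray:
        return np.array([o.centroid for o in self.observations])

    def areas(self) -> np.ndarray:
        return np.array([o.area_px for o in self.observations], dtype=float)

    def major_axes(self) -> np.ndarray:
        return np.array([o.major_axis_px for o in self.observations])


def link_track(
    masks: Sequence[Optional[np.ndarray]], max_gap: int = 1
) -> CellTrack:
    """Link per-frame masks of the single in-channel cell into one track.

    Consecutive detections are linked when their masks overlap; gaps of up to
    ``max_gap`` missing/unlinked frames are bridged. A detection with zero
    overlap beyond the allowed gap splits the track: the part built so far is
    returned with a warning (channels hold one cell, so a split indicates a
    segmentation failure, not a second cell).
    """
    detections = [
        (k, m) for k, m in enumerate(masks) if m is not None and np.asarray(m).any()
    ]
    if len(detections) < 2:
        raise ValueError("need detections in at least two frames")

    obs = [CellObservation.from_mask(*detections[0])]
    skipped = [k for k in range(detections[0][0]) ]
    for k, mask in detections[1:]:
        prev = obs[-1]
        gap = k - prev.frame_index - 1
        overlap = int(np.logical_and(prev.mask, mask).sum())
        if overlap == 0:
            if gap > max_gap:
                warnings.warn(
                    f"track split at frame {k}: no mask overlap after a gap of "
                    f"{gap} frames; keeping the earlier segment",
                    stacklevel=2,
                )
                break
            if gap == 0:
                warnings.warn(
                    f"zero mask overlap between consecutive frames "
                    f"{prev.frame_index}->{k}; linking by adjacency",
                    stacklevel=2,
                )
        elif gap > max_gap:
            warnings.warn(
                f"track split at frame {k}: gap of {gap} frames exceeds "
                f"max_gap={max_gap}",
                stacklevel=2,
            )
            break
        skipped.extend(range(prev.frame_index + 1, k))
        obs.append(CellObservation.from_mask(k, mask))

    _assign_movement_signs(obs)
    return CellTrack(observations=obs, skipped_frames=skipped)


def _assign_movement_signs(obs: list[CellObservation], window: int = 3) -> None:
    """Majority sign of the channel-axis centroid displacement over the last
    ``window`` steps; robust to single-frame jitter."""
    rows = np.array([o.centroid[0] for o in obs])
    steps = np.sign(np.diff(rows))
    for i, o in enumerate(obs):
        recent = steps[max(0, i - window) : i]
        if recent.size == 0:
            recent = steps[:window]
        s = np.sum(recent)
        o.movement_sign = int(np.sign(s))


def loess_smooth(
    y: np.ndarray,
    span: float = 0.1,
    degree: int = 2,
    x: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Loess: local regression with tricube weights and a polynomial model.

    Matches the classic formulation (weighted linear least squares on the
    ``span`` fraction of nearest points, second-degree polynomial by
    default). NaNs are ignored during fitting and preserved in the output.
    A local polynomial fit reproduces any polynomial of the same or lower
    degree exactly, so constants and linear trends pass through unchanged.
    """
    y = np.asarray(y, dtype=float)
    if x is None:
        x = np.arange(y.size, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    xo, yo = x[ok], y[ok]
    n = xo.size
    out = np.full(y.size, np.nan)
    if n == 0:
        return out
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    idx_ok = np.flatnonzero(ok)
    for j, i in enumerate(idx_ok):
        d = np.abs(xo - x[i])
        sel = np.argsort(d, kind="stable")[:k]
        dmax = d[sel].max()
        if dmax == 0:
            out[i] = yo[sel].mean()
            continue
        w = (1.0 - (d[sel] / dmax) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        xs = xo[sel] - x[i]
        V = np.vander(xs, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], yo[sel] * sw, rcond=None)
        out[i] = coef[0]
    return out


def compute_kinematics(
    track: CellTrack,
    frame_interval_s: float,
    pixel_size_um: float,
    reference_frame: Optional[int] = None,
    span: float = 0.1,
) -> CellTrack:
    """Fill speed, smoothed speed and relative length/area on a track.

    Raw speed divides the centroid displacement between consecutive frames by
    the frame interval; steps across skipped frames are left undefined.
    Smoothing is loess (degree 2, ``span`` of the data length). Relative
    length and area are normalized to the observation at ``reference_frame``
    (default: the first observation), which is by construction exactly 1
    there.
    """
    if len(track) < 3:
        raise ValueError("track must have at least 3 observations")
    frames = track.frame_indices()
    cents = track.centroids()
    n = len(track)
    speed = np.full(n, np.nan)
    dgap = np.diff(frames)
    disp = np.linalg.norm(np.diff(cents, axis=0), axis=1) * pixel_size_um
    contiguous = dgap == 1
    speed[1:][contiguous] = disp[contiguous] / frame_interval_s
    track.speed_um_s = speed
    track.speed_smoothed = loess_smooth(speed, span=span, x=frames.astype(float))

    if reference_frame is None:
        ref_pos = 0
    else:
        hits = np.flatnonzero(frames == reference_frame)
        if hits.size == 0:
            raise ValueError(f"reference frame {reference_frame} not in track")
        ref_pos = int(hits[0])
    lengths = track.major_axes()
    areas = track.areas()
    track.rel_length = lengths / lengths[ref_pos]
    track.rel_area = areas / areas[ref_pos]
    return track


def signed_axial_velocity(
    track: CellTrack,
    frame_interval_s: float,
    pixel_size_um: float,
    reference_sign: Optional[int] = None,
    n_reference_steps: int = 5,
) -> np.ndarray:
    """Channel-axis centroid velocity, positive along the original direction.

    The sign convention is set by the net pre-existing motion (the first
    ``n_reference_steps`` steps by default), so a direction reversal shows up
    as a zero crossing from + to -. Central differences are used so the
    velocity sample at frame k reflects the motion *at* t_k rather than over
    the preceding interval (a forward difference would bias the interpolated
    stall time late by half a frame).
    """
    rows = track.centroids()[:, 0]
    frames = track.frame_indices().astype(float)
    v_rows = np.full(rows.size, np.nan)
    central = np.flatnonzero(
        (np.diff(frames)[:-1] == 1) & (np.diff(frames)[1:] == 1)
    ) + 1
    v_rows[central] = (
        (rows[central + 1] - rows[central - 1]) / 2.0 * pixel_size_um / frame_interval_s
    )
    if rows.size >= 2 and frames[1] - frames[0] == 1:
        v_rows[0] = (rows[1] - rows[0]) * pixel_size_um / frame_interval_s
    if rows.size >= 2 and frames[-1] - frames[-2] == 1:
        v_rows[-1] = (rows[-1] - rows[-2]) * pixel_size_um / frame_interval_s
    if reference_sign is None:
        net = np.nansum(v_rows[1 : 1 + n_reference_steps])
        reference_sign = int(np.sign(net)) or 1
    return v_rows * reference_sign


def locate_rear_target(
    mask: np.ndarray,
    movement_direction: tuple[float, float],
    target_angle_deg: float = 180.0,
) -> tuple[int, int]:
    """Boundary point of the cell at a target angle from its movement vector.

    The stimulation targeter: with the default 180 degrees the returned
    perimeter pixel lies opposite the direction of motion, i.e. at the cell
    rear. Among boundary pixels the one whose direction from the centroid is
    angularly closest to the target is chosen; ties go to the farther pixel,
    then lexicographic (row, col) order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    dvec = np.asarray(movement_direction, dtype=float)
    if np.allclose(dvec, 0):
        raise ValueError("zero movement direction")

    from scipy import ndimage

    boundary = mask & ~ndimage.binary_erosion(mask)
    rr, cc = np.nonzero(boundary)
    crow, ccol = np.nonzero(mask)
    centroid = (crow.mean(), ccol.mean())

    base = np.arctan2(dvec[0], dvec[1])
    target = base + np.deg2rad(target_angle_deg)
    ang = np.arctan2(rr - centroid[0], cc - centroid[1])
    diff = np.abs(np.angle(np.exp(1j * (ang - target))))
    dist = np.hypot(rr - centroid[0], cc - centroid[1])
    # minimal angular difference, then max distance, then (row, col)
    order = np.lexsort((cc, rr, -dist, np.round(diff, 9)))
    best = order[0]
    return int(rr[best]), int(cc[best])
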