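"""Seeded synthetic microscopy of polarized cells migrating in 1D channels.

The generator produces a forward model of the study system: one elongated
neutrophil-like cell per straight vertical channel, carrying a front-polarized
activity gradient (FRET mode) or a rear-polarized myosin reporter (myosin
mode). At t = 0 an optogenetic stimulus is applied at the cell rear and the
cell responds according to its response class:

``no_response``
    activity, polarity and motion are unchanged;
``medium``
    the rear activity rises by a few percent but the front never engages;
``strong``
    both edges engage and the cell transiently reverses direction, then
    recovers its original polarity after the stimulus ends;
``reversed``
    the rear rises, the front decays, the cell stalls and reverses direction
    *before* the two edge activities cross, and it stays reversed;
``reverser`` / ``non_reverser``
    the persistent-stimulation counterparts of ``reversed`` / ``no_response``.

All event times (rear response, front response, stall, cross-point) are
configured on the kinetics object and realized exactly by the piecewise-linear
trace model, so downstream detectors can be verified against a known schedule.
Rendering maps the ground-truth activity through the camera model
``dark_offset + illumination x signal (+ ratio bias on the acceptor) + noise``
and is bit-reproducible for a fixed (parameters, seed) pair.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile

from .core import AcquisitionParams, FrameStack

CLASS_LABELS = ("no_response", "medium", "strong", "reversed", "reverser", "non_reverser")

#: Transient (12-pulse) assay: pulses at t = 0, 3, ..., 33 s.
TRANSIENT_STIM_END_S = 33.0
#: Center (5-pulse) assay: pulses at t = 0, 3, ..., 12 s.
CENTER_STIM_END_S = 12.0

# Baseline activity levels (acceptor/donor ratio units). The front-rear
# contrast of 0.2 ratio units is large against the 0.03 front-engagement
# threshold and small against zero, mimicking a clearly polarized cell.
_REAR0 = 0.95
_FRONT0 = 1.15

# Activity profile along the cell axis: flat plateaus over the rear and front
# thirds with a smoothstep ramp between, so edge-region measurements read the
# edge trace values directly.
_PLATEAU = 0.35


@dataclass
class CellKinetics:
    """Ground-truth response kinetics of one synthetic cell.

    The event fields are the *schedule the detectors should recover*: e.g.
    ``rear_rise_onset_s`` is the time at which rear activity has risen 1%
    above its t = 0 value, matching the event-detection definition.
    """

    class_label: str = "reversed"
    baseline_speed_um_s: float = 0.14
    front_rear_ratio0: float = _FRONT0 / _REAR0
    rear_rise_onset_s: float = 5.0
    front_decay_onset_s: float = 20.0
    stall_time_s: float = 27.0
    crosspoint_time_s: float = 51.0
    myosin_rear_fraction: float = 0.45
    rear_baseline: float = _REAR0
    medium_rise_fraction: float = 0.04
    myosin_lag_s: float = 6.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"invalid class label {self.class_label!r}")
        if not 0.0 <= self.myosin_rear_fraction <= 1.0:
            raise ValueError("myosin_rear_fraction must lie in [0, 1]")
        if self.class_label in ("reversed", "reverser"):
            sched = (
                self.rear_rise_onset_s,
                self.front_decay_onset_s,
                self.stall_time_s,
                self.crosspoint_time_s,
            )
            if not all(a < b for a, b in zip(sched, sched[1:])):
                raise ValueError(
                    "reversed-class event schedule must be strictly ordered "
                    "rear_rise < front_decay < stall < crosspoint"
                )

    @property
    def rear0(self) -> float:
        return self.rear_baseline

    @property
    def front0(self) -> float:
        return self.rear_baseline * self.front_rear_ratio0


def default_kinetics(class_label: str, **overrides) -> CellKinetics:
    """Study-condition kinetics for a response class.

    Event medians for the reversed class follow the observed cohort medians
    (stall 27 s, cross-point 51 s); the strong class engages both edges with a
    sub-0.03 activity gap and flips direction only transiently; the medium
    class caps its rear rise at 4% with the front untouched.
    """
    base: dict = {"class_label": class_label}
    if class_label in ("no_response", "non_reverser"):
        pass
    elif class_label == "medium":
        base.update(rear_rise_onset_s=5.0)
    elif class_label == "strong":
        base.update(rear_rise_onset_s=3.0, front_decay_onset_s=14.0, stall_time_s=27.0)
    elif class_label in ("reversed", "reverser"):
        base.update(
            rear_rise_onset_s=5.0,
            front_decay_onset_s=20.0,
            stall_time_s=27.0,
            crosspoint_time_s=51.0,
        )
    else:
        raise ValueError(f"invalid class label {class_label!r}")
    base.update(overrides)
    return CellKinetics(**base)


# ---------------------------------------------------------------------------
# Piecewise-linear trace model
# ---------------------------------------------------------------------------


def _hold_interp(t: np.ndarray, pts: Sequence[tuple[float, float]]) -> np.ndarray:
    xs = np.array([p[0] for p in pts], dtype=float)
    ys = np.array([p[1] for p in pts], dtype=float)
    return np.interp(t, xs, ys)


def _trace_breakpoints(kin: CellKinetics, stim_end_s: float, t_end: float):
    """Breakpoint lists (t, value) for rear, front and signed velocity.

    Signed velocity is positive along the original direction of motion.
    Within each class the slopes are solved so that the configured event
    schedule is met exactly by the detection definitions (1% threshold
    crossings relative to the t = 0 values, velocity zero crossing, trace
    intersection).
    """
    r0, f0 = kin.rear0, kin.front0
    v0 = kin.baseline_speed_um_s
    label = kin.class_label
    tau = 9.0  # half-width of the velocity reversal ramp, s

    if label in ("no_response", "non_reverser"):
        rear = [(0.0, r0)]
        front = [(0.0, f0)]
        vel = [(0.0, v0)]

    elif label == "medium":
        # Rear rises from t=0 and crosses the +1% detection level at the
        # configured onset; capped at the class rise fraction; relaxes back
        # after the stimulus ends.
        sr = 0.01 * r0 / kin.rear_rise_onset_s
        cap = r0 * (1.0 + kin.medium_rise_fraction)
        t_cap = (cap - r0) / sr
        rear = [(0.0, r0), (t_cap, cap), (stim_end_s + 3.0, cap), (stim_end_s + 23.0, r0)]
        front = [(0.0, f0)]
        vel = [(0.0, v0)]

    elif label == "strong":
        t_rec = stim_end_s + 3.0
        sr = 0.01 * r0 / kin.rear_rise_onset_s
        rear_max = r0 + sr * t_rec
        # Front decays over a short 4 s lead-in to its 1% detection crossing.
        df = kin.front_decay_onset_s - 4.0
        sf = 0.01 * f0 / 4.0
        front_min = f0 - sf * (t_rec - df)
        rear = [(0.0, r0), (t_rec, rear_max), (t_rec + 20.0, r0)]
        front = [(0.0, f0), (df, f0), (t_rec, front_min), (t_rec + 20.0, f0)]
        st = kin.stall_time_s
        vel = [
            (0.0, v0),
            (st - tau, v0),
            (st + tau, -v0),
            (stim_end_s + 9.0, -v0),
            (stim_end_s + 21.0, v0),
        ]

    elif label in ("reversed", "reverser"):
        t_rear = kin.rear_rise_onset_s
        t_front = kin.front_decay_onset_s
        t_cross = kin.crosspoint_time_s
        sr = 0.01 * r0 / t_rear
        sf = (f0 - r0 - sr * t_cross - 0.01 * f0) / (t_cross - t_front)
        if sf <= 0:
            raise ValueError(
                "event schedule infeasible: front slope non-positive; move the "
                "cross-point later or the front response earlier"
            )
        df = t_front - 0.01 * f0 / sf
        if df < 0:
            raise ValueError("event schedule infeasible: front decay would start pre-stimulus")
        rear = [(0.0, r0), ((f0 - r0) / sr, f0)]
        front = [(0.0, f0), (df, f0), (df + (f0 - r0) / sf, r0)]
        st = kin.stall_time_s
        vel = [(0.0, v0), (st - tau, v0), (st + tau, -v0)]

    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"invalid class label {label!r}")

    def pad(pts):
        return [(-1e9, pts[0][1])] + list(pts) + [(max(1e9, t_end), pts[-1][1])]

    return pad(rear), pad(front), pad(vel)


# ---------------------------------------------------------------------------
# Track-level simulation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTrack:
    """Ground truth for one simulated cell: geometry, traces and profiles."""

    kinetics: CellKinetics
    acq: AcquisitionParams
    time_s: np.ndarray
    stim_frame: int
    stim_end_s: float
    centroid_row: np.ndarray
    centroid_col: np.ndarray
    half_length_px: float
    half_width_px: float
    rear_trace: np.ndarray
    front_trace: np.ndarray
    velocity_um_s: np.ndarray  # signed, + along original direction of motion
    activity_profiles: np.ndarray  # (T, 2*half_length+1), rear -> front
    myosin_profiles: np.ndarray
    seed: int
    mask_exponent: float = 4.0

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    def length_px(self) -> float:
        return 2.0 * self.half_length_px


def _axis_profile_shape(n_axis: int) -> np.ndarray:
    """Normalized rear->front shape g(q): 0 on the rear third, 1 on the front
    third, smoothstep between."""
    q = np.linspace(0.0, 1.0, n_axis)
    s = np.clip((q - _PLATEAU) / (1.0 - 2.0 * _PLATEAU), 0.0, 1.0)
    return 3.0 * s**2 - 2.0 * s**3


def _myosin_weight(g: np.ndarray, polarity: float, m_rear: float) -> np.ndarray:
    """Myosin intensity shape for a given polarity state in [-1, 1]."""
    w = (1.0 - g) * max(polarity, 0.0) + g * max(-polarity, 0.0)
    return 1.0 + (m_rear - 1.0) * w


def simulate_cell_track(
    kinetics: CellKinetics,
    acq: AcquisitionParams,
    n_frames: int = 51,
    stim_frame: int = 21,
    stim_mode: str = "transient",
    seed: int = 0,
    half_length_px: float = 55.0,
    half_width_px: float = 11.0,
    start_row: Optional[float] = None,
    start_col: Optional[float] = None,
    mask_exponent: float = 4.0,
) -> SyntheticTrack:
    """Simulate the ground-truth track of one cell.

    The cell migrates "up" the channel (decreasing row index) before
    stimulation; its original front is therefore the low-row end. The centroid
    path is the time integral of the signed velocity trace and the per-frame
    1D activity/myosin profiles realize the class kinetics exactly.

    Parameters
    ----------
    n_frames : total frame count (>= 2).
    stim_frame : index of the frame at t = 0 (first pulse); preceded by
        ``stim_frame`` unstimulated frames.
    stim_mode : "transient" (12 pulses), "persistent", or "center" (5 pulses).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if stim_mode not in ("transient", "persistent", "center"):
        raise ValueError(f"unknown stim_mode {stim_mode!r}")
    dt = acq.frame_interval_s
    t = (np.arange(n_frames) - stim_frame) * dt
    t_end = float(t[-1])
    stim_end = {
        "transient": TRANSIENT_STIM_END_S,
        "center": CENTER_STIM_END_S,
        "persistent": max(t_end, 0.0) + dt,
    }[stim_mode]

    rear_pts, front_pts, vel_pts = _trace_breakpoints(kinetics, stim_end, t_end)
    rear = _hold_interp(t, rear_pts)
    front = _hold_interp(t, front_pts)
    vel = _hold_interp(t, vel_pts)

    # Centroid path: trapezoidal integral of the signed velocity; motion along
    # the original direction decreases the row index.
    px_per_s = 1.0 / acq.pixel_size_um
    disp_px = np.concatenate(
        [[0.0], np.cumsum(0.5 * (vel[1:] + vel[:-1]) * dt * px_per_s)]
    )
    if start_row is None:
        # place the start so the whole trajectory (including any reversal)
        # sits centered inside the field
        lo_needed = half_length_px + 1.0
        hi_allowed = acq.field_shape[0] - half_length_px - 2.0
        span = disp_px.max() - disp_px.min()
        if span > hi_allowed - lo_needed:
            raise ValueError(
                "trajectory span exceeds the field; enlarge field_shape or "
                "shorten the run"
            )
        slack = (hi_allowed - lo_needed - span) / 2.0
        start_row = lo_needed + slack + disp_px.max()
    centroid_row = start_row - disp_px
    if start_col is None:
        start_col = acq.field_shape[1] / 2.0
    centroid_col = np.full(n_frames, float(start_col))

    n_axis = int(2 * half_length_px + 1)
    g = _axis_profile_shape(n_axis)
    profiles = rear[:, None] + (front - rear)[:, None] * g[None, :]

    f0_minus_r0 = kinetics.front0 - kinetics.rear0
    if f0_minus_r0 == 0:
        f0_minus_r0 = 1.0  # unpolarized cell: polarity factor stays at 0
    m_rear = (
        1.5 * kinetics.myosin_rear_fraction / (1.0 - 1.5 * kinetics.myosin_rear_fraction)
        if kinetics.myosin_rear_fraction < 2.0 / 3.0
        else 4.0
    )
    t_lag = t - kinetics.myosin_lag_s
    front_lag = _hold_interp(t_lag, front_pts)
    rear_lag = _hold_interp(t_lag, rear_pts)
    polarity = np.clip((front_lag - rear_lag) / f0_minus_r0, -1.0, 1.0)
    myosin = np.stack([_myosin_weight(g, p, m_rear) for p in polarity])

    return SyntheticTrack(
        kinetics=kinetics,
        acq=acq,
        time_s=t,
        stim_frame=stim_frame,
        stim_end_s=stim_end,
        centroid_row=centroid_row,
        centroid_col=centroid_col,
        half_length_px=half_length_px,
        half_width_px=half_width_px,
        rear_trace=rear,
        front_trace=front,
        velocity_um_s=vel,
        activity_profiles=profiles,
        myosin_profiles=myosin,
        seed=seed,
        mask_exponent=mask_exponent,
    )


def track_region_traces(
    track: SyntheticTrack,
    noise_sd: float = 0.0,
    velocity_noise_sd: float = 0.0,
    seed: Optional[int] = None,
):
    """Measurement-like front/rear traces and signed velocity from a track.

    Returns ``(time_s, front, rear, velocity)`` with optional i.i.d. Gaussian
    noise, emulating region-level measurement at the generator's trace level.
    """
    rng = np.random.default_rng(track.seed if seed is None else seed)
    front = track.front_trace.copy()
    rear = track.rear_trace.copy()
    vel = track.velocity_um_s.copy()
    if noise_sd > 0:
        front = front + rng.normal(0.0, noise_sd, front.size)
        rear = rear + rng.normal(0.0, noise_sd, rear.size)
    if velocity_noise_sd > 0:
        vel = vel + rng.normal(0.0, velocity_noise_sd, vel.size)
    return track.time_s.copy(), front, rear, vel


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def superellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    half_axes: tuple[float, float],
    exponent: float = 4.0,
) -> np.ndarray:
    """Axially elongated super-ellipse binary mask on a pixel grid."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    a, b = half_axes
    return (
        np.abs((rr - center[0]) / a) ** exponent + np.abs((cc - center[1]) / b) ** exponent
    ) <= 1.0


@dataclass
class SyntheticScene:
    """Rendered frames plus the full ground truth that produced them."""

    frames: FrameStack
    truth_masks: np.ndarray  # (T, rows, cols) bool
    truth_profiles: np.ndarray  # (T, n_axis) activity rear -> front
    truth_kinetics: CellKinetics
    track: SyntheticTrack
    seed: int

    def __post_init__(self) -> None:
        if not self.truth_masks.any(axis=(1, 2)).all():
            raise ValueError("truth masks must be nonempty in every frame")


def render_frames(
    track: SyntheticTrack,
    acq: Optional[AcquisitionParams] = None,
    seed: int = 0,
    mode: str = "fret",
    base_intensity: float = 600.0,
    allow_edge_clip: bool = False,
) -> tuple[FrameStack, np.ndarray]:
    """Render a ground-truth track into a two-channel image stack.

    Each channel is ``dark_offset + illumination x signal`` with the ratio
    bias additionally multiplied into the acceptor channel; Poisson shot noise
    (on the illumination-scaled signal) and Gaussian read noise are applied
    when enabled. In FRET mode the donor signal is uniform ``base_intensity``
    inside the mask and the acceptor equals donor times the activity, so the
    noise-free flat-field acceptor/donor ratio reproduces the ground truth
    exactly. Returns ``(FrameStack, truth_masks)``.
    """
    acq = track.acq if acq is None else acq
    if mode not in ("fret", "myosin"):
        raise ValueError(f"unknown mode {mode!r}")
    nr, nc = acq.field_shape
    T = track.n_frames
    a, b = track.half_length_px, track.half_width_px

    if not allow_edge_clip:
        lo_r = track.centroid_row - a
        hi_r = track.centroid_row + a
        if lo_r.min() < -0.5 or hi_r.max() > nr - 0.5:
            raise ValueError("track extends outside the field along the channel axis")
        if track.centroid_col.min() - b < -0.5 or track.centroid_col.max() + b > nc - 0.5:
            raise ValueError("track extends outside the field across the channel")

    ill_a, ill_b = (
        acq.illumination_field
        if acq.illumination_field is not None
        else (np.ones((nr, nc)), np.ones((nr, nc)))
    )
    bias = acq.ratio_bias_field if acq.ratio_bias_field is not None else np.ones((nr, nc))

    rng = np.random.default_rng(seed)
    ch_a = np.empty((T, nr, nc))
    ch_b = np.empty((T, nr, nc))
    masks = np.zeros((T, nr, nc), dtype=bool)
    rr = np.arange(nr, dtype=float)
    n_axis = track.activity_profiles.shape[1]

    for k in range(T):
        center = (track.centroid_row[k], track.centroid_col[k])
        mask = superellipse_mask((nr, nc), center, (a, b), track.mask_exponent)
        if not mask.any():
            raise ValueError(f"cell mask empty in frame {k} (fully outside field)")
        masks[k] = mask
        # q: 0 at the original-rear end (high row), 1 at the original front.
        q_rows = np.clip((center[0] + a - rr) / (2.0 * a), 0.0, 1.0)
        idx = np.clip((q_rows * (n_axis - 1)).round().astype(int), 0, n_axis - 1)
        act_rows = track.activity_profiles[k][idx]
        myo_rows = track.myosin_profiles[k][idx]

        sig_a = np.where(mask, base_intensity, 0.0)
        if mode == "fret":
            sig_b = np.where(mask, base_intensity * act_rows[:, None], 0.0)
        else:
            sig_a = np.where(mask, base_intensity * myo_rows[:, None], 0.0)
            sig_b = np.where(mask, base_intensity, 0.0)

        fa = ill_a * sig_a
        fb = ill_b * bias * sig_b if mode == "fret" else ill_b * sig_b
        if acq.poisson:
            fa = rng.poisson(np.clip(fa, 0, None)).astype(float)
            fb = rng.poisson(np.clip(fb, 0, None)).astype(float)
        fa = fa + acq.dark_offset
        fb = fb + acq.dark_offset
        if acq.gaussian_sd > 0:
            fa = fa + rng.normal(0.0, acq.gaussian_sd, fa.shape)
            fb = fb + rng.normal(0.0, acq.gaussian_sd, fb.shape)
        ch_a[k] = fa
        ch_b[k] = fb

    # Stimulation log: rear-edge target per stimulated frame.
    stim_targets = []
    n_stim = int(min(track.stim_end_s, track.time_s[-1]) // acq.frame_interval_s) + 1
    for j in range(max(n_stim, 0)):
        k = track.stim_frame + j
        if k >= T:
            break
        stim_targets.append((k, float(track.centroid_row[k] + a), float(track.centroid_col[k])))
    stack = FrameStack(
        channel_a=ch_a,
        channel_b=ch_b,
        acq=acq,
        stim_frame=track.stim_frame,
        stim_targets=stim_targets,
        mode=mode,
    )
    return stack, masks


def simulate_scene(
    kinetics: CellKinetics,
    acq: AcquisitionParams,
    n_frames: int = 51,
    stim_frame: int = 21,
    stim_mode: str = "transient",
    seed: int = 0,
    mode: str = "fret",
    **track_kwargs,
) -> SyntheticScene:
    """Simulate one cell and render it: the end-to-end generator entry point."""
    track = simulate_cell_track(
        kinetics, acq, n_frames=n_frames, stim_frame=stim_frame, stim_mode=stim_mode,
        seed=seed, **track_kwargs,
    )
    frames, masks = render_frames(track, acq, seed=seed, mode=mode)
    return SyntheticScene(
        frames=frames,
        truth_masks=masks,
        truth_profiles=track.activity_profiles,
        truth_kinetics=kinetics,
        track=track,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Transient-assay class proportions observed in the untreated cohort
#: (n = 261): 56% no response, 21% medium, 7% strong, 6% reversed; the
#: remaining 10% did not meet tracking QC and are folded into no_response
#: when a full mix is required.
STUDY_CLASS_MIX = {"no_response": 0.56, "medium": 0.21, "strong": 0.07, "reversed": 0.06}


def derive_cell_seed(master_seed: int, cell_index: int) -> int:
    """Stable per-cell seed from (master seed, cell index).

    Hash-derived so that reordering or subsetting a cohort never changes any
    cell's own stream.
    """
    h = hashlib.blake2b(f"{master_seed}:{cell_index}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "little") % (2**31)


def simulate_cohort(
    class_mix: dict[str, float],
    n_cells: int,
    acq: AcquisitionParams,
    seed: int = 0,
    n_frames: int = 51,
    stim_frame: int = 21,
    stim_mode: str = "transient",
    mode: str = "fret",
    render: bool = True,
):
    """Simulate a seeded cohort of cells with classes drawn from ``class_mix``.

    Class labels are assigned by a single multinomial-style draw from the
    master seed; each cell then uses its own hash-derived seed. With
    ``render=False`` only ground-truth tracks are built (no image stacks),
    which is the cheap path for trace-level cohort studies.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    labels_avail = list(class_mix)
    probs = np.array([class_mix[c] for c in labels_avail], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("class mix proportions must be nonnegative and sum to 1")
    for c in labels_avail:
        if c not in CLASS_LABELS:
            raise ValueError(f"invalid class label {c!r}")
    rng = np.random.default_rng(seed)
    labels = rng.choice(labels_avail, size=n_cells, p=probs)

    scenes = []
    for i, label in enumerate(labels):
        cell_seed = derive_cell_seed(seed, i)
        kin = default_kinetics(str(label))
        if render:
            scenes.append(
                simulate_scene(
                    kin, acq, n_frames=n_frames, stim_frame=stim_frame,
                    stim_mode=stim_mode, seed=cell_seed, mode=mode,
                )
            )
        else:
            scenes.append(
                simulate_cell_track(
                    kin, acq, n_frames=n_frames, stim_frame=stim_frame,
                    stim_mode=stim_mode, seed=cell_seed,
                )
            )
    return scenes


def simulate_center_stim_cohort(
    n_cells: int,
    responder_fraction: float,
    seed: int = 0,
    n_frames: int = 51,
    stim_frame: int = 21,
    frame_interval_s: float = 3.0,
    noise_sd: float = 0.01,
    amplitude_mean: float = 0.08,
    amplitude_sd: float = 0.03,
):
    """Whole-cell activity traces for the center-stimulation assay.

    Responders show a triangular activity bump that starts at stimulation
    onset, peaks near 15 s (just after the last of the 5 pulses) and returns
    to baseline by 30 s; non-responders stay flat. Every trace carries i.i.d.
    Gaussian measurement noise. Returns ``(time_s, traces, is_responder)``
    with ``traces`` of shape (n_cells, n_frames).
    """
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = (np.arange(n_frames) - stim_frame) * frame_interval_s
    is_resp = rng.random(n_cells) < responder_fraction
    traces = np.ones((n_cells, n_frames))
    for i in range(n_cells):
        if is_resp[i]:
            amp = max(rng.normal(amplitude_mean, amplitude_sd), 0.02)
            peak = rng.uniform(12.0, 18.0)
            up = np.clip(t / peak, 0.0, None)
            down = np.clip((30.0 - t) / (30.0 - peak), 0.0, None)
            traces[i] += amp * np.clip(np.minimum(up, down), 0.0, 1.0)
    traces += rng.normal(0.0, noise_sd, traces.shape)
    return t, traces, is_resp


# ---------------------------------------------------------------------------
# On-disk scene format
# ---------------------------------------------------------------------------


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> Path:
    """Write a scene as per-channel multi-page TIFFs + JSON sidecar + truth CSV.

    Layout matches the pipeline's expected one-directory-per-cell dataset:
    ``donor.tif``/``acceptor.tif`` (or ``myosin.tif``/``cyto.tif``),
    ``meta.json`` and ``truth_events.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fs = scene.frames
    names = ("donor", "acceptor") if fs.mode == "fret" else ("myosin", "cyto")
    tifffile.imwrite(out / f"{names[0]}.tif", fs.channel_a.astype(np.float32))
    tifffile.imwrite(out / f"{names[1]}.tif", fs.channel_b.astype(np.float32))
    kin = scene.truth_kinetics
    meta = {
        "mode": fs.mode,
        "stim_end_s": scene.track.stim_end_s,
        "stim_mode": (
            "persistent" if scene.track.stim_end_s > scene.track.time_s[-1] else "transient"
        ),
        "frame_interval_s": fs.acq.frame_interval_s,
        "pixel_size_um": fs.acq.pixel_size_um,
        "field_shape": list(fs.acq.field_shape),
        "dark_offset": fs.acq.dark_offset,
        "stim_frame": fs.stim_frame,
        "stim_targets": [list(x) for x in fs.stim_targets],
        "seed": scene.seed,
        "truth": {
            "class_label": kin.class_label,
            "baseline_speed_um_s": kin.baseline_speed_um_s,
            "front_rear_ratio0": kin.front_rear_ratio0,
            "myosin_rear_fraction": kin.myosin_rear_fraction,
        },
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    with open(out / "truth_events.csv", "w") as fh:
        fh.write("event,time_s\n")
        fh.write(f"rear_response,{kin.rear_rise_onset_s}\n")
        fh.write(f"front_response,{kin.front_decay_onset_s}\n")
        fh.write(f"stall,{kin.stall_time_s}\n")
        fh.write(f"crosspoint,{kin.crosspoint_time_s}\n")
    return out
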