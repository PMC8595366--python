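"""Acquisition metadata and the two-channel image-stack container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Default frame interval of the time-lapse acquisition (images every 3 s).
DEFAULT_FRAME_INTERVAL_S = 3.0
#: Default pixel size of the 60x objective / sCMOS camera combination.
DEFAULT_PIXEL_SIZE_UM = 0.21


@dataclass
class AcquisitionParams:
    """Physical and camera parameters of a two-channel time-lapse acquisition.

    Parameters
    ----------
    frame_interval_s:
        Time between consecutive frames, seconds. Imaging and stimulation
        alternate on this clock.
    pixel_size_um:
        Size of one pixel in micrometers.
    field_shape:
        Image shape as (rows, cols). The microfluidic channel runs along the
        row (vertical) axis.
    dark_offset:
        Camera dark-state offset in counts, added to every pixel.
    illumination_field:
        Optional per-channel multiplicative illumination maps
        ``(donor_map, acceptor_map)``; ``None`` means flat illumination.
    ratio_bias_field:
        Optional multiplicative map applied to the acceptor channel only,
        modelling the field-dependent bias in apparent FRET ratio caused by
        light-path imperfections. ``None`` means no bias.
    gaussian_sd:
        Read-noise standard deviation in counts (0 disables).
    poisson:
        If True, shot noise is drawn per pixel on the illumination-scaled
        signal.
    """

    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    field_shape: tuple[int, int] = (256, 64)
    dark_offset: float = 100.0
    illumination_field: Optional[tuple[np.ndarray, np.ndarray]] = None
    ratio_bias_field: Optional[np.ndarray] = None
    gaussian_sd: float = 0.0
    poisson: bool = False

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if len(self.field_shape) != 2 or any(int(s) <= 0 for s in self.field_shape):
            raise ValueError("field_shape must be a positive (rows, cols) pair")
        self.field_shape = (int(self.field_shape[0]), int(self.field_shape[1]))
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be non-negative")
        if self.illumination_field is not None:
            for m in self.illumination_field:
                self._check_map(np.asarray(m), "illumination_field")
        if self.ratio_bias_field is not None:
            self._check_map(np.asarray(self.ratio_bias_field), "ratio_bias_field")

    def _check_map(self, m: np.ndarray, name: str) -> None:
        if m.shape != self.field_shape:
            raise ValueError(f"{name} shape {m.shape} != field_shape {self.field_shape}")
        if not np.all(m > 0):
            raise ValueError(f"{name} must be strictly positive")


@dataclass
class FrameStack:
    """A two-channel fluorescence time series with its stimulation log.

    ``channel_a``/``channel_b`` are (T, rows, cols) float arrays. In FRET mode
    they are the donor and acceptor channels; in myosin mode the myosin
    reporter and the cytosolic tag.
    """

    channel_a: np.ndarray
    channel_b: np.ndarray
    acq: AcquisitionParams
    stim_frame: int
    stim_targets: list[tuple[int, float, float]] = field(default_factory=list)
    mode: str = "fret"

    def __post_init__(self) -> None:
        a = np.asarray(self.channel_a, dtype=float)
        b = np.asarray(self.channel_b, dtype=float)
        if a.shape != b.shape or a.ndim != 3:
            raise ValueError("channels must be equal-shaped (T, rows, cols) arrays")
        if a.shape[1:] != self.acq.field_shape:
            raise ValueError("frame shape does not match acquisition field_shape")
        if self.mode not in ("fret", "myosin"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.channel_a = a
        self.channel_b = b

    @property
    def n_frames(self) -> int:
        return self.channel_a.shape[0]

    def times_s(self) -> np.ndarray:
        """Frame times in seconds with t = 0 at the first stimulation pulse."""
        k = np.arange(self.n_frames)
        return (k - self.stim_frame) * self.acq.frame_interval_s
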