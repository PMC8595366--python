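"""Analysis configuration: defaults, YAML loading and validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Union

import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults encode the study conditions: 3 s frame interval, 0.21 um pixels,
    800 px edge regions, a 6-frame (15 s) pre-stimulus baseline window, 1%
    event-detection thresholds taken relative to the t = 0 value, a 2% rear
    rise and a 0.03 ratio-unit front-engagement gap for response
    classification, and the four center-stimulation analysis windows.
    """

    frame_interval_s: float = 3.0
    pixel_size_um: float = 0.21
    baseline_window_frames: int = 6
    event_rise_fraction: float = 0.01
    class_rear_rise_fraction: float = 0.02
    front_engagement_gap: float = 0.03
    region_size_px: int = 800
    window_control1_s: tuple[float, float] = (-60.0, -42.0)
    window_control2_s: tuple[float, float] = (-39.0, -21.0)
    window_control3_s: tuple[float, float] = (-18.0, 0.0)
    peak_search_s: tuple[float, float] = (3.0, 33.0)
    peak_half_width_s: float = 9.0
    smoothing_p: float = 0.5
    loess_span: float = 0.1
    min_object_px: int = 200
    apply_ratio_correction: bool = False
    stall_final_window_s: float = 15.0
    speed_only_classification: bool = False  # myosin line under ROCK inhibition

    def __post_init__(self) -> None:
        for name in ("frame_interval_s", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "event_rise_fraction",
            "class_rear_rise_fraction",
            "front_engagement_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("baseline_window_frames", "region_size_px", "min_object_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 <= self.smoothing_p <= 1.0:
            raise ValueError("smoothing_p must lie in [0, 1]")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span must lie in (0, 1]")
        windows = {
            "window_control1_s": tuple(self.window_control1_s),
            "window_control2_s": tuple(self.window_control2_s),
            "window_control3_s": tuple(self.window_control3_s),
            "peak_search_s": tuple(self.peak_search_s),
        }
        for name, (a, b) in windows.items():
            if not a < b:
                raise ValueError(f"{name} must be an increasing (start, end) pair")
            setattr(self, name, (float(a), float(b)))
        names = list(windows)
        for i, ni in enumerate(names):
            for nj in names[i + 1 :]:
                a, b = windows[ni]
                c, d = windows[nj]
                if max(a, c) < min(b, d):
                    raise ValueError(f"windows overlap: {ni} and {nj}")
        if self.peak_half_width_s <= 0:
            raise ValueError("peak_half_width_s must be positive")


def validate_config(source: Union[str, Path, dict, None]) -> AnalysisConfig:
    """Load and validate a configuration from YAML (path), dict, or None.

    Missing keys take the defaults; unknown keys are rejected so typos fail
    loudly rather than silently running with defaults.
    """
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)
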