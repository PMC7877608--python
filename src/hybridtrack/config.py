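"""Configuration objects for the hybrid tracker.

All tunable parameters of the pipeline live here as nested dataclasses with
documented defaults.  Configuration files are flat ``key: value`` YAML using
dotted keys (``motion.min_area``, ``exit.tau_bar``, ...) mirroring the nested
structure; :func:`load_config` / :func:`save_config` round-trip them.

Spatial parameters are in pixels, temporal parameters in frames unless a unit
is stated.  The two anchors are ``insect_area`` (expected visible body area of
the focal species, px) and ``insect_length`` (expected body length, px):
several defaults derive from them — the minimum blob area is a quarter of the
body area, the initial association gate ``gating.d_int`` is one body length,
and so is the frame-edge margin used when classifying disappearances.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "MotionConfig",
    "GatingConfig",
    "OcclusionConfig",
    "ExitConfig",
    "TrackerConfig",
    "Calibration",
    "load_config",
    "save_config",
]


@dataclass
class MotionConfig:
    """Motion-channel (background subtraction) parameters.

    min_area
        Minimum blob area in pixels for a foreground component to count as a
        candidate detection.  Default: ``0.25 × insect_area`` (tolerates
        partial occlusion while rejecting pixel noise).
    median_kernel
        Odd side length of the square median filter applied to the raw mask.
    erosion_kernel
        Side length of the square structuring element of the binary erosion
        applied after the median filter.
    warmup_frames
        Number of initial frames during which the background model is still
        settling; masks are forced to all-background.
    region_change_floor
        Minimum area (px) of a connected changed region for it to count when
        enumerating "regions of inter-frame change".
    """

    min_area: float = 64.0
    median_kernel: int = 5
    erosion_kernel: int = 3
    warmup_frames: int = 30
    region_change_floor: int = 2

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.warmup_frames < 1:
            raise ValueError("warmup_frames must be >= 1")


@dataclass
class GatingConfig:
    """Association-gate parameters (maximum detection thresholds).

    d_int
        Initial motion-channel gate, set to the average body length of the
        target species in pixels.
    tau_bar
        Threshold number of consecutive undetected frames after which the
        appearance-channel gate starts to widen and disappearance
        classification is triggered.
    """

    d_int: float = 40.0
    tau_bar: int = 15


@dataclass
class OcclusionConfig:
    #: number of most recent motion-channel area measurements fitted by the
    #: least-squares area trend (~167 ms at 60 fps)
    window: int = 10


@dataclass
class ExitConfig:
    """Field-of-view exit estimator parameters.

    tau_bar
        Consecutive undetected frames before the exit probability is
        evaluated (mirrors ``gating.tau_bar``).
    beta_bar
        Exit-probability threshold in percent; above it the track is paused.
    edge_margin
        Distance (px) from a frame boundary within which a disappearance is
        treated as a possible exit rather than an occlusion.  ``None`` means
        one body length (``insect_length``).
    """

    tau_bar: int = 15
    beta_bar: float = 85.0
    edge_margin: float | None = None


@dataclass
class Calibration:
    """Spatial/temporal scale of the recording: pixels per millimetre and
    frames per second.  Supplied by the user (e.g. from a ruler placed in the
    scene); never inferred."""

    pixels_per_mm: float
    fps: float

    def __post_init__(self) -> None:
        if self.pixels_per_mm <= 0:
            raise ValueError("pixels_per_mm must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")


@dataclass
class TrackerConfig:
    """Top-level tracker configuration.

    insect_area / insect_length anchor the scale-dependent defaults (see
    module docstring).  ``max_regions_for_motion`` is the mode-switch
    compromise: with up to this many regions of local change the cheap motion
    channel is trusted, beyond it the appearance channel takes over.
    """

    insect_area: float = 1465.0
    insect_length: float = 42.0
    max_regions_for_motion: int = 3
    min_confidence: float = 0.5
    #: tracks at least this long (seconds) are flagged for analysis
    min_track_seconds: float = 2.0
    fps: float = 60.0
    motion: MotionConfig = field(default_factory=MotionConfig)
    gating: GatingConfig = field(default_factory=GatingConfig)
    occlusion: OcclusionConfig = field(default_factory=OcclusionConfig)
    exit: ExitConfig = field(default_factory=ExitConfig)

    def __post_init__(self) -> None:
        if self.max_regions_for_motion < 1:
            raise ValueError("max_regions_for_motion must be >= 1")

    @classmethod
    def for_insect(
        cls, insect_area: float, insect_length: float, **overrides: Any
    ) -> "TrackerConfig":
        """Build a config with scale-dependent defaults derived from the
        expected body area and length of the focal species."""
        cfg = cls(insect_area=insect_area, insect_length=insect_length, **overrides)
        cfg.motion.min_area = max(1.0, 0.25 * insect_area)
        cfg.gating.d_int = insect_length
        return cfg

    @property
    def edge_margin(self) -> float:
        m = self.exit.edge_margin
        return self.insect_length if m is None else m


# ---------------------------------------------------------------------------
# flat-key YAML round trip


def _flatten(obj: Any, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f in dataclasses.fields(obj):
        val = getattr(obj, f.name)
        key = f"{prefix}{f.name}"
        if dataclasses.is_dataclass(val):
            out.update(_flatten(val, prefix=f"{key}."))
        else:
            out[key] = val
    return out


def save_config(cfg: TrackerConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as flat-key YAML."""
    Path(path).write_text(yaml.safe_dump(_flatten(cfg), sort_keys=True))


def load_config(path: str | Path) -> TrackerConfig:
    """Load a flat-key YAML config; unspecified keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    cfg = TrackerConfig()
    for key, value in raw.items():
        target: Any = cfg
        *parents, leaf = key.split(".")
        for part in parents:
            if not hasattr(target, part):
                raise KeyError(f"unknown config section {part!r} in key {key!r}")
            target = getattr(target, part)
        if not dataclasses.is_dataclass(target) or not any(
            f.name == leaf for f in dataclasses.fields(target)
        ):
            raise KeyError(f"unknown config key {key!r}")
        setattr(target, leaf, value)
    return cfg
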