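"""Configuration objects for the rig, the mask, and every pipeline stage.

Threshold defaults follow DIN EN ISO 15007-style event-detection practice
(2 deg dispersion / 120 ms / 30 deg/s for fixations, 90 deg/s for saccades)
and the study conventions of the simulated-hemianopia driving setup: a
180 deg frontal view on three 3400x2720 px panels, gaze sampled at 60 Hz,
driving data at 240 Hz, a 10 Hz low-pass on horizontal gaze, peripheral-scan
eccentricity thresholds of 30 and 45 deg, a 100 m brake-search distance with
a 41.76 m fallback, and a central zone of +-5 deg excluded from hemifield
statistics.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, fields


class ConfigError(ValueError):
    """Raised when a configuration value is outside its physical bounds."""


@dataclass
class RigGeometry:
    """Three flat panels, each tangent to the viewing circle at its center
    azimuth and subtending 60 deg, tiling the frontal 180 deg without gaps.

    ``vertical_half_angle_deg`` is derived from the pixel aspect ratio of a
    panel: atan((H/W) * tan(30 deg)) ~= 24.79 deg.
    """

    panel_count: int = 3
    panel_px_w: int = 3400
    panel_px_h: int = 2720
    panel_half_angle_deg: float = 30.0
    panel_center_azimuths: tuple[float, ...] = (-60.0, 0.0, 60.0)

    @property
    def vertical_half_angle_deg(self) -> float:
        aspect = self.panel_px_h / self.panel_px_w
        return math.degrees(
            math.atan(aspect * math.tan(math.radians(self.panel_half_angle_deg)))
        )

    def validate(self) -> None:
        if self.panel_count != len(self.panel_center_azimuths):
            raise ConfigError("panel_count must match panel_center_azimuths")
        if self.panel_px_w <= 0 or self.panel_px_h <= 0:
            raise ConfigError("panel pixel dimensions must be positive")
        if not 0 < self.panel_half_angle_deg < 90:
            raise ConfigError("panel_half_angle_deg must be in (0, 90)")


@dataclass
class MaskSpec:
    """Hemianopic occlusion overlay: which side is blind, how wide the
    semitransparent fade between masked and unmasked field is, and the
    mid-gray fill that matches road/building luminance."""

    side: str = "left"
    fade_width_deg: float = 4.0
    mask_color: tuple[int, int, int] = (96, 96, 96)
    update_rate_hz: float = 60.0

    def validate(self) -> None:
        if self.side not in ("left", "right"):
            raise ConfigError(f"mask side must be 'left' or 'right', got {self.side!r}")
        if not 0 <= self.fade_width_deg < 180:
            raise ConfigError("fade_width_deg must be in [0, 180)")


@dataclass
class BufferPolicy:
    """Anchor smoothing: moving average over ``window_len`` samples, bypassed
    outright for gaze movements larger than ``bypass_threshold_deg`` so that
    large scans relocate the mask within one frame; invalid samples hold the
    last anchor."""

    window_len: int = 3
    bypass_threshold_deg: float = 10.0
    hold_on_invalid: bool = True

    def validate(self) -> None:
        if self.window_len < 1:
            raise ConfigError("window_len must be >= 1")
        if self.bypass_threshold_deg <= 0:
            raise ConfigError("bypass_threshold_deg must be > 0")


@dataclass
class FilterConfig:
    """Low-pass on the horizontal gaze channel. Offline analysis uses a
    zero-phase filter (no onset lag); ``order`` is the per-pass Butterworth
    order."""

    cutoff_hz: float = 10.0
    order: int = 2
    sample_rate_hz: float = 60.0
    zero_phase: bool = True
    min_segment_samples: int = 5

    def validate(self) -> None:
        if self.cutoff_hz >= self.sample_rate_hz / 2:
            raise ConfigError(
                f"cutoff {self.cutoff_hz} Hz must be below Nyquist "
                f"({self.sample_rate_hz / 2} Hz)"
            )
        if self.cutoff_hz <= 0 or self.order < 1:
            raise ConfigError("cutoff must be > 0 and order >= 1")


@dataclass
class EventConfig:
    dispersion_deg: float = 2.0
    min_fixation_s: float = 0.120
    fixation_vmax_deg_s: float = 30.0
    saccade_vmin_deg_s: float = 90.0
    central_deg: float = 5.0

    def validate(self) -> None:
        if self.dispersion_deg <= 0 or self.min_fixation_s <= 0:
            raise ConfigError("dispersion and minimum duration must be positive")
        if not 0 < self.fixation_vmax_deg_s < self.saccade_vmin_deg_s:
            raise ConfigError("need 0 < fixation_vmax < saccade_vmin")


@dataclass
class MetricsConfig:
    scan_threshold_small_deg: float = 30.0
    scan_threshold_large_deg: float = 45.0
    central_deg: float = 5.0
    endpoint_deg: float = 5.0
    brake_search_m: float = 100.0
    fallback_dist_m: float = 41.76
    lane_boundary_cm: float = 85.0
    lane_variance_units: str = "cm2"

    def validate(self) -> None:
        if self.fallback_dist_m > self.brake_search_m:
            raise ConfigError("fallback distance must not exceed brake-search distance")
        if self.lane_boundary_cm <= 0:
            raise ConfigError("lane_boundary_cm must be positive")
        if self.lane_variance_units not in ("cm2", "m2"):
            raise ConfigError("lane_variance_units must be 'cm2' or 'm2'")


@dataclass
class ProjectConfig:
    """One object that fully describes a processing run; a run is reproducible
    from (config, seed, inputs)."""

    rig: RigGeometry = field(default_factory=RigGeometry)
    mask: MaskSpec = field(default_factory=MaskSpec)
    buffer: BufferPolicy = field(default_factory=BufferPolicy)
    filter: FilterConfig = field(default_factory=FilterConfig)
    events: EventConfig = field(default_factory=EventConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    gaze_rate_hz: float = 60.0
    drive_rate_hz: float = 240.0
    version: str = "1"

    def validate(self) -> None:
        for section in (self.rig, self.mask, self.buffer, self.filter,
                        self.events, self.metrics):
            section.validate()
        if self.gaze_rate_hz <= 0 or self.drive_rate_hz <= 0:
            raise ConfigError("sample rates must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ProjectConfig":
        sections = {
            "rig": RigGeometry,
            "mask": MaskSpec,
            "buffer": BufferPolicy,
            "filter": FilterConfig,
            "events": EventConfig,
            "metrics": MetricsConfig,
        }
        kwargs: dict = {}
        for key, value in (data or {}).items():
            if key in sections:
                section_cls = sections[key]
                allowed = {f.name for f in fields(section_cls)}
                unknown = set(value) - allowed
                if unknown:
                    raise ConfigError(
                        f"unknown keys in config section {key!r}: {sorted(unknown)}"
                    )
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                kwargs[key] = section_cls(**coerced)
            elif key in {f.name for f in fields(cls)}:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown config section {key!r}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
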