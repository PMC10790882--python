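"""Gaze-to-panel geometry and the hemianopic moving-mask engine.

The rig presents a 180 deg frontal view on three flat panels (3400 x 2720 px
each) whose centers sit at azimuths -60, 0 and +60 deg; every azimuth in
[-90, 90) belongs to exactly one panel.  Gaze arrives as a unit direction
vector from the virtual eye position; its horizontal angle anchors a 2D
overlay that occludes the complete left or right half of the visual field,
with a semitransparent linear fade across the boundary.  Anchor motion is
smoothed with a short moving-average buffer that is bypassed for large gaze
movements (so big scans relocate the mask within one 60 Hz frame) and held
at the last value during signal loss.

Angle conventions: azimuth is signed, negative = left, 0 = straight ahead;
elevation is positive upward.  Pixel origin is the top-left corner of a
panel, x rightward, y downward; anchors are kept at fractional pixels.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BufferPolicy, MaskSpec, RigGeometry

__all__ = [
    "GazeDirection",
    "PanelAnchor",
    "vector_to_azel",
    "azel_to_vector",
    "azel_to_panel_pixel",
    "panel_pixel_to_azel",
    "AnchorSmoother",
    "smooth_anchor",
    "opacity_at",
    "occluded_fraction",
    "replay_mask",
]


@dataclass
class GazeDirection:
    """Unit gaze vector (z forward, x rightward, y upward) with validity."""

    x: float
    y: float
    z: float
    valid: bool = True


@dataclass
class PanelAnchor:
    """Pixel anchor of the mask overlay on one panel."""

    panel_index: int
    px_x: float
    px_y: float
    held: bool = False
    clamped: bool = False


def vector_to_azel(x, y, z):
    """Convert gaze direction vectors to (azimuth, elevation) in degrees.

    Accepts scalars or arrays.  Returns ``(az, el, valid)`` where invalid
    (zero-length or non-finite) vectors yield NaN angles and ``valid=False``
    so that downstream hold-last-sample policies apply instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    norm = np.sqrt(x * x + y * y + z * z)
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(norm) & (norm > 1e-9)
    norm_safe = np.where(valid, norm, 1.0)
    az = np.degrees(np.arctan2(x, z))
    el = np.degrees(np.arcsin(np.clip(y / norm_safe, -1.0, 1.0)))
    az = np.where(valid, az, np.nan)
    el = np.where(valid, el, np.nan)
    if az.ndim == 0:
        return float(az), float(el), bool(valid)
    return az, el, valid


def azel_to_vector(az_deg, el_deg):
    """Inverse of :func:`vector_to_azel`; returns unit (x, y, z)."""
    az = np.radians(np.asarray(az_deg, dtype=float))
    el = np.radians(np.asarray(el_deg, dtype=float))
    x = np.cos(el) * np.sin(az)
    y = np.sin(el)
    z = np.cos(el) * np.cos(az)
    return x, y, z


def _panel_index(az_deg: float, rig: RigGeometry) -> int:
    # half-open sectors [-90,-30), [-30,30), [30,90]; right panel owns +30
    half = rig.panel_half_angle_deg
    if az_deg < -half:
        return 0
    if az_deg < half:
        return 1
    return 2


def azel_to_panel_pixel(az_deg: float, el_deg: float, rig: RigGeometry) -> PanelAnchor:
    """Map a gaze angle to a fractional pixel anchor on the owning panel.

    Azimuths outside +-90 deg are clamped to the nearest field edge and the
    anchor is flagged ``clamped``; elevations are clamped to the vertical
    panel extent likewise.
    """
    clamped = False
    if not -90.0 <= az_deg <= 90.0:
        az_deg = min(90.0, max(-90.0, az_deg))
        clamped = True
    v_half = rig.vertical_half_angle_deg
    if not -v_half <= el_deg <= v_half:
        el_deg = min(v_half, max(-v_half, el_deg))
        clamped = True
    panel = _panel_index(az_deg, rig)
    center = rig.panel_center_azimuths[panel]
    tan_half = np.tan(np.radians(rig.panel_half_angle_deg))
    px_x = rig.panel_px_w / 2.0 * (1.0 + np.tan(np.radians(az_deg - center)) / tan_half)
    px_y = rig.panel_px_h / 2.0 * (
        1.0 - np.tan(np.radians(el_deg)) / np.tan(np.radians(v_half))
    )
    return PanelAnchor(panel, float(px_x), float(px_y), held=False, clamped=clamped)


def panel_pixel_to_azel(panel_index: int, px_x: float, px_y: float,
                        rig: RigGeometry) -> tuple[float, float]:
    """Inverse mapping used for round-trip checks."""
    center = rig.panel_center_azimuths[panel_index]
    tan_half = np.tan(np.radians(rig.panel_half_angle_deg))
    az = center + np.degrees(
        np.arctan((2.0 * px_x / rig.panel_px_w - 1.0) * tan_half)
    )
    v_half = rig.vertical_half_angle_deg
    el = np.degrees(
        np.arctan((1.0 - 2.0 * px_y / rig.panel_px_h) * np.tan(np.radians(v_half)))
    )
    return float(az), float(el)


class AnchorSmoother:
    """Streaming anchor filter implementing buffer, bypass, and hold-last.

    Output is the arithmetic mean of the last ``window_len`` valid azimuths,
    except that a movement larger than ``bypass_threshold_deg`` relative to
    the previous output resets the buffer and passes the newest sample
    through unsmoothed, and an invalid sample repeats the previous output
    with the ``held`` flag set.
    """

    def __init__(self, policy: BufferPolicy | None = None):
        self.policy = policy or BufferPolicy()
        self.policy.validate()
        self._buf: deque[float] = deque(maxlen=self.policy.window_len)
        self._out: float | None = None

    def update(self, az_deg: float, valid: bool = True) -> tuple[float, bool]:
        if not valid or az_deg is None or not np.isfinite(az_deg):
            if self._out is None:
                return 0.0, True  # no history yet: hold at rig center
            return self._out, True
        if self._out is not None and abs(az_deg - self._out) > self.policy.bypass_threshold_deg:
            self._buf.clear()
        self._buf.append(float(az_deg))
        self._out = float(np.mean(self._buf))
        return self._out, False

    @property
    def output(self) -> float | None:
        return self._out


def smooth_anchor(azimuths, valid=None, policy: BufferPolicy | None = None) -> float:
    """Run the anchor smoother over a history and return the final azimuth.

    ``azimuths`` is a sequence of gaze azimuths in degrees; ``valid`` an
    optional boolean sequence of the same length (defaults to all valid).
    An all-invalid history holds the anchor at the rig center (0 deg) with a
    warning.
    """
    azimuths = np.asarray(azimuths, dtype=float)
    if azimuths.size == 0:
        raise ValueError("history must be non-empty")
    if valid is None:
        valid = np.isfinite(azimuths)
    sm = AnchorSmoother(policy)
    out, held = 0.0, True
    for a, v in zip(azimuths, np.asarray(valid, dtype=bool)):
        out, held = sm.update(a, v)
    if sm.output is None:
        warnings.warn("all gaze samples invalid; anchor held at rig center")
        return 0.0
    return out


def opacity_at(az_deg, anchor_az_deg: float, spec: MaskSpec):
    """Mask opacity (0 transparent .. 1 opaque) at a field azimuth.

    For ``side='left'`` the field left of ``anchor - fade/2`` is fully
    occluded and the fade ramps linearly down to transparent at
    ``anchor + fade/2``; mirror-symmetric for ``side='right'``.  A zero fade
    width gives a hard edge (opacity 0.5 exactly on the boundary).
    """
    spec.validate()
    az = np.asarray(az_deg, dtype=float)
    anchor = float(anchor_az_deg)
    fade = spec.fade_width_deg
    if fade == 0.0:
        if spec.side == "left":
            alpha = np.where(az < anchor, 1.0, np.where(az > anchor, 0.0, 0.5))
        else:
            alpha = np.where(az > anchor, 1.0, np.where(az < anchor, 0.0, 0.5))
    else:
        if spec.side == "left":
            alpha = np.clip((anchor + fade / 2.0 - az) / fade, 0.0, 1.0)
        else:
            alpha = np.clip((az - (anchor - fade / 2.0)) / fade, 0.0, 1.0)
    if alpha.ndim == 0:
        return float(alpha)
    return alpha


def occluded_fraction(anchor_az_deg: float, spec: MaskSpec,
                      field: tuple[float, float] = (-90.0, 90.0)) -> float:
    """Mean opacity over the horizontal field (closed-form integral).

    Diagnostic for mask correctness: with a symmetric linear fade fully
    inside the field this equals the fade-0 value, e.g. (anchor + 90)/180
    for a left-sided mask over [-90, 90].
    """
    spec.validate()
    lo, hi = field
    if not lo < hi:
        raise ValueError("field must be a non-empty interval")
    if not lo <= anchor_az_deg <= hi:
        raise ValueError("anchor must lie within the field")
    fade = spec.fade_width_deg
    a = anchor_az_deg - fade / 2.0
    b = anchor_az_deg + fade / 2.0

    def ramp_integral() -> float:
        lo2, hi2 = max(a, lo), min(b, hi)
        if hi2 <= lo2:
            return 0.0
        alpha_lo = opacity_at(lo2, anchor_az_deg, spec)
        alpha_hi = opacity_at(hi2, anchor_az_deg, spec)
        return 0.5 * (alpha_lo + alpha_hi) * (hi2 - lo2)

    if spec.side == "left":
        full = max(0.0, min(a, hi) - lo)
    else:
        full = max(0.0, hi - max(b, lo))
    return (full + ramp_integral()) / (hi - lo)


def replay_mask(gaze: pd.DataFrame, rig: RigGeometry | None = None,
                spec: MaskSpec | None = None,
                policy: BufferPolicy | None = None) -> pd.DataFrame:
    """Replay a gaze log through the mask engine offline at the log's rate.

    ``gaze`` must carry columns ``time``, ``az`` and optionally ``el`` and
    ``valid``.  Returns one anchor record per input sample with columns
    ``time, anchor_az, panel, px_x, px_y, held, lag_samples`` where
    ``lag_samples`` counts samples since the last unheld anchor (0 while
    tracking).  Replay is deterministic: identical logs and configs give
    bit-identical output.
    """
    rig = rig or RigGeometry()
    spec = spec or MaskSpec()
    rig.validate()
    spec.validate()
    times = np.asarray(gaze["time"], dtype=float)
    diffs = np.diff(times)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        raise ValueError(f"non-monotone timestamp at index {int(bad[0]) + 1}")
    az = np.asarray(gaze["az"], dtype=float)
    el = np.asarray(gaze["el"], dtype=float) if "el" in gaze else np.zeros_like(az)
    valid = (
        np.asarray(gaze["valid"], dtype=bool)
        if "valid" in gaze
        else np.isfinite(az)
    )
    valid = valid & np.isfinite(az)

    sm = AnchorSmoother(policy)
    records = []
    last_el = 0.0
    lag = 0
    for t, a, e, v in zip(times, az, el, valid):
        out, held = sm.update(a, v)
        if v and np.isfinite(e):
            last_el = float(e)
        lag = lag + 1 if held else 0
        anchor = azel_to_panel_pixel(out, last_el, rig)
        records.append(
            (t, out, anchor.panel_index, anchor.px_x, anchor.px_y, held, lag)
        )
    return pd.DataFrame(
        records,
        columns=["time", "anchor_az", "panel", "px_x", "px_y", "held", "lag_samples"],
    )
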