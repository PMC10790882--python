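"""Deceleration-phase segmentation and all per-scenario driving/gaze measures.

Each intersection approach is reduced to its deceleration phase: from the
first brake activation found within 100 m of the intersection (fallback:
41.76 m before it, the typical deceleration onset 3 s ahead at 50 km/h) to
the zebra crossing (distance 0).  Within that window the module computes
lateral-guidance measures (mean/variance of the lane-position offset, lane
crossings over a configurable boundary), scanning measures (side of the
first peripheral gaze beyond 30 or 45 deg, missing large scans at the 45 deg
criterion, horizontal gaze variance/min/max/mean), hemispace fixation counts
and durations beyond the central 10 deg, and directional saccade amplitudes
(endpoint eccentricity beyond 5 deg).  Gaze (60 Hz) and driving (240 Hz)
streams are aligned by timestamp; the window is defined on driving time and
applied to gaze as the closed interval [t_start, t_end].
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .config import EventConfig, MetricsConfig
from .events import Fixation, Saccade, detect_fixations, detect_saccades

__all__ = [
    "ScenarioWindow",
    "ScenarioMetrics",
    "segment_deceleration",
    "lane_metrics",
    "first_peripheral_scan",
    "missing_large_scans",
    "gaze_summary",
    "hemispace_fixations",
    "directional_saccades",
    "compute_scenario_metrics",
    "aggregate",
    "percentage",
]


@dataclass
class ScenarioWindow:
    t_start: float
    t_end: float
    trigger: str  # brake | fallback


@dataclass
class ScenarioMetrics:
    """One row per subject x vision condition x intersection maneuver."""

    subject: str = ""
    condition: str = ""      # NV | LHH | RHH
    intersection: str = ""   # SCI | LTI | RTI
    trigger: str = ""
    phase_duration: float = np.nan
    lane_mean: float = np.nan
    lane_variance: float = np.nan
    lane_crossings: int = 0
    first_scan_30: str = "none"
    first_scan_45: str = "none"
    missing_large_scan_left: bool = False
    missing_large_scan_right: bool = False
    gaze_var: float = np.nan
    gaze_mean: float = np.nan
    gaze_min: float = np.nan
    gaze_max: float = np.nan
    fix_n_left: int = 0
    fix_n_right: int = 0
    fix_dur_left: float = np.nan
    fix_dur_right: float = np.nan
    sacc_amp_left: float = np.nan
    sacc_amp_right: float = np.nan
    n_fixations: int = 0
    n_saccades: int = 0


def segment_deceleration(drive: pd.DataFrame,
                         cfg: MetricsConfig | None = None) -> ScenarioWindow:
    """Locate the deceleration phase of one intersection approach.

    ``drive`` needs ``time``, ``dist`` (m, decreasing to 0 at the zebra
    crossing) and ``brake`` (bool).  The phase starts at the first braking
    sample with dist <= 100 m, or — when no braking occurs in that range —
    at the first sample with dist <= 41.76 m (``trigger='fallback'``).
    """
    cfg = cfg or MetricsConfig()
    time = np.asarray(drive["time"], dtype=float)
    dist = np.asarray(drive["dist"], dtype=float)
    brake = np.asarray(drive["brake"], dtype=bool)
    reached = np.nonzero(dist <= 0.0)[0]
    if reached.size == 0:
        raise ValueError("approach never reaches the intersection (dist = 0)")
    i_end = int(reached[0])
    cand = np.nonzero(brake[: i_end + 1] & (dist[: i_end + 1] <= cfg.brake_search_m))[0]
    if cand.size:
        return ScenarioWindow(float(time[cand[0]]), float(time[i_end]), "brake")
    fb = np.nonzero(dist[: i_end + 1] <= cfg.fallback_dist_m)[0]
    if fb.size == 0:
        raise ValueError(
            f"approach never reaches the fallback distance "
            f"({cfg.fallback_dist_m} m)"
        )
    return ScenarioWindow(float(time[fb[0]]), float(time[i_end]), "fallback")


def lane_metrics(drive: pd.DataFrame, cfg: MetricsConfig | None = None
                 ) -> tuple[float, float, int]:
    """Mean and sample variance of lane offset, plus lane-crossing count.

    A crossing is an entry (upward crossing) into |offset| > boundary; a
    trace that starts outside the boundary does not count its initial state.
    Variance is reported in cm^2 by default, configurable to m^2.
    """
    cfg = cfg or MetricsConfig()
    offset = np.asarray(drive["lane_offset"], dtype=float)
    if offset.size == 0:
        raise ValueError("empty deceleration window")
    mean = float(offset.mean())
    var = float(offset.var(ddof=1)) if offset.size > 1 else 0.0
    if cfg.lane_variance_units == "m2":
        var /= 1e4
    outside = np.abs(offset) > cfg.lane_boundary_cm
    entries = int(np.sum(outside[1:] & ~outside[:-1]))
    return mean, var, entries


def _window_gaze(gaze: pd.DataFrame, window: ScenarioWindow) -> pd.DataFrame:
    t = np.asarray(gaze["time"], dtype=float)
    inside = (t >= window.t_start) & (t <= window.t_end)
    return gaze.loc[inside]


def _usable_az(gaze: pd.DataFrame) -> np.ndarray:
    col = "az_filt" if "az_filt" in gaze else "az"
    az = np.asarray(gaze[col], dtype=float)
    if "excluded" in gaze:
        az = az[~np.asarray(gaze["excluded"], dtype=bool)]
    return az[np.isfinite(az)]


def first_peripheral_scan(gaze: pd.DataFrame, threshold_deg: float) -> str:
    """Side of the earliest unexcluded sample at or beyond the eccentricity
    threshold; 'none' if the trace never reaches it."""
    col = "az_filt" if "az_filt" in gaze else "az"
    az = np.asarray(gaze[col], dtype=float)
    keep = np.isfinite(az)
    if "excluded" in gaze:
        keep &= ~np.asarray(gaze["excluded"], dtype=bool)
    idx = np.nonzero(keep & (np.abs(az) >= threshold_deg))[0]
    if idx.size == 0:
        return "none"
    return "left" if az[idx[0]] < 0 else "right"


def missing_large_scans(gaze: pd.DataFrame,
                        threshold_deg: float = 45.0) -> tuple[bool, bool]:
    """(left, right) flags: True when no sample reaches -/+ threshold."""
    az = _usable_az(gaze)
    if az.size == 0:
        return True, True
    return bool(az.min() > -threshold_deg), bool(az.max() < threshold_deg)


def gaze_summary(gaze: pd.DataFrame) -> tuple[float, float, float, float]:
    """(variance, mean, min, max) of horizontal gaze position in degrees.

    Sample variance (n-1).  Fewer than 2 usable samples give NaNs.
    """
    az = _usable_az(gaze)
    if az.size < 2:
        return np.nan, np.nan, np.nan, np.nan
    return (
        float(az.var(ddof=1)),
        float(az.mean()),
        float(az.min()),
        float(az.max()),
    )


def hemispace_fixations(fixations: list[Fixation], central_deg: float = 5.0
                        ) -> tuple[int, int, float, float]:
    """Fixation count and mean duration per hemifield beyond the central
    10 deg (|mean azimuth| <= 5 deg counts neither side)."""
    left = [f for f in fixations if f.mean_az < -central_deg]
    right = [f for f in fixations if f.mean_az > central_deg]
    dur_left = float(np.mean([f.duration for f in left])) if left else np.nan
    dur_right = float(np.mean([f.duration for f in right])) if right else np.nan
    return len(left), len(right), dur_left, dur_right


def directional_saccades(saccades: list[Saccade], endpoint_deg: float = 5.0
                         ) -> tuple[float, float]:
    """Mean amplitude of saccades into each periphery: leftward saccades
    ending beyond -5 deg and rightward saccades ending beyond +5 deg."""
    left = [s.amplitude for s in saccades
            if s.direction == "left" and s.endpoint_az < -endpoint_deg]
    right = [s.amplitude for s in saccades
             if s.direction == "right" and s.endpoint_az > endpoint_deg]
    amp_left = float(np.mean(left)) if left else np.nan
    amp_right = float(np.mean(right)) if right else np.nan
    return amp_left, amp_right


def compute_scenario_metrics(gaze: pd.DataFrame, drive: pd.DataFrame,
                             metrics_cfg: MetricsConfig | None = None,
                             event_cfg: EventConfig | None = None,
                             subject: str = "", condition: str = "",
                             intersection: str = "") -> ScenarioMetrics:
    """All measures of one scenario; ``gaze`` must be preprocessed."""
    metrics_cfg = metrics_cfg or MetricsConfig()
    event_cfg = event_cfg or EventConfig()
    window = segment_deceleration(drive, metrics_cfg)
    t = np.asarray(drive["time"], dtype=float)
    dwin = drive.loc[(t >= window.t_start) & (t <= window.t_end)]
    gwin = _window_gaze(gaze, window)

    lane_mean, lane_var, crossings = lane_metrics(dwin, metrics_cfg)
    # events are detected on the full stream (so window edges do not truncate
    # them) and attributed to the window by their onset time
    fixations = [f for f in detect_fixations(gaze, event_cfg)
                 if window.t_start <= f.t_start <= window.t_end + 1e-9]
    saccades = [s for s in detect_saccades(gaze, event_cfg)
                if window.t_start <= s.t_start <= window.t_end + 1e-9]
    var, mean, mn, mx = gaze_summary(gwin)
    nl, nr, dl, dr = hemispace_fixations(fixations, metrics_cfg.central_deg)
    al, ar = directional_saccades(saccades, metrics_cfg.endpoint_deg)
    miss_l, miss_r = missing_large_scans(
        gwin, metrics_cfg.scan_threshold_large_deg
    )
    return ScenarioMetrics(
        subject=subject,
        condition=condition,
        intersection=intersection,
        trigger=window.trigger,
        phase_duration=window.t_end - window.t_start,
        lane_mean=lane_mean,
        lane_variance=lane_var,
        lane_crossings=crossings,
        first_scan_30=first_peripheral_scan(gwin, metrics_cfg.scan_threshold_small_deg),
        first_scan_45=first_peripheral_scan(gwin, metrics_cfg.scan_threshold_large_deg),
        missing_large_scan_left=miss_l,
        missing_large_scan_right=miss_r,
        gaze_var=var,
        gaze_mean=mean,
        gaze_min=mn,
        gaze_max=mx,
        fix_n_left=nl,
        fix_n_right=nr,
        fix_dur_left=dl,
        fix_dur_right=dr,
        sacc_amp_left=al,
        sacc_amp_right=ar,
        n_fixations=len(fixations),
        n_saccades=len(saccades),
    )


def records_frame(records: list[ScenarioMetrics]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


_NUMERIC = [
    "phase_duration", "lane_mean", "lane_variance", "lane_crossings",
    "gaze_var", "gaze_mean", "gaze_min", "gaze_max",
    "fix_n_left", "fix_n_right", "fix_dur_left", "fix_dur_right",
    "sacc_amp_left", "sacc_amp_right", "n_fixations", "n_saccades",
]


def aggregate(records: pd.DataFrame | list[ScenarioMetrics]) -> dict:
    """Condition x intersection summaries plus count/percentage tables.

    Returns a dict with a ``summary`` DataFrame (mean and SD of every
    numeric measure), count tables for first-scan side, missing large
    scans and lane crossings, with percentages computed via
    :func:`percentage`.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if df.empty:
        raise ValueError("no scenario records to aggregate")
    numeric = [c for c in _NUMERIC if c in df.columns]
    summary = (
        df.groupby(["condition", "intersection"], sort=True)[numeric]
        .agg(["mean", "std"])
    )

    def per_condition_counts(col: str, values) -> pd.DataFrame:
        rows = []
        for cond, group in df.groupby("condition", sort=True):
            total = len(group)
            for v in values:
                k = int((group[col] == v).sum())
                rows.append(
                    {"condition": cond, col: v, "k": k, "K": total,
                     "pct": percentage(k, total)}
                )
        return pd.DataFrame(rows)

    out = {
        "summary": summary,
        "first_scan_30": per_condition_counts("first_scan_30",
                                              ["left", "right", "none"]),
        "first_scan_45": per_condition_counts("first_scan_45",
                                              ["left", "right", "none"]),
        "missing_scans": _missing_counts(df),
        "lane_crossings": {
            "scenarios_with_crossing": int((df["lane_crossings"] > 0).sum()),
            "total_scenarios": int(len(df)),
            "total_crossings": int(df["lane_crossings"].sum()),
            "pct_scenarios": percentage(int((df["lane_crossings"] > 0).sum()),
                                        int(len(df))),
        },
    }
    return out


def _missing_counts(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    n_total = len(df)
    for side, col in (("left", "missing_large_scan_left"),
                      ("right", "missing_large_scan_right")):
        pooled = 0
        for cond, group in df.groupby("condition", sort=True):
            k = int(group[col].sum())
            pooled += k
            rows.append({"condition": cond, "side": side, "k": k,
                         "K": len(group), "pct": percentage(k, len(group))})
        rows.append({"condition": "pooled", "side": side, "k": pooled,
                     "K": n_total, "pct": percentage(pooled, n_total)})
    return pd.DataFrame(rows)


def percentage(k: int, total: int) -> float:
    """100*k/K rounded half-up to two decimals; K = 0 yields NaN."""
    if total == 0:
        return float("nan")
    if not 0 <= k <= total:
        raise ValueError("need 0 <= k <= K")
    frac = Decimal(100) * Decimal(k) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
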