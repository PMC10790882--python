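"""Fixation and saccade classification on the filtered horizontal gaze signal.

Fixations follow a dispersion-duration rule with a conjunctive velocity
check (I-DT style, per DIN EN ISO 15007 practice): a candidate window of at
least 120 ms qualifies when the horizontal position spans no more than 2 deg
AND every sample speed stays below 30 deg/s; the window is extended to the
right while both conditions hold.  Saccades are maximal runs of samples with
speed >= 90 deg/s; their amplitude is the horizontal displacement between
the first and last run sample.  Samples with intermediate speeds belong to
neither class.  Excluded samples terminate events; dispersion is measured on
the horizontal azimuth only.

Durations are sample-count durations: an event covering n samples at rate fs
lasts n/fs seconds, so a 1 s trace of constant gaze yields one fixation of
duration 1.0 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EventConfig
from .preprocess import _contiguous_segments

__all__ = ["Fixation", "Saccade", "velocity", "detect_fixations",
           "detect_saccades", "events_to_frame"]


@dataclass
class Fixation:
    t_start: float
    t_end: float
    duration: float
    mean_az: float
    hemifield: str  # left | central | right


@dataclass
class Saccade:
    t_start: float
    t_end: float
    amplitude: float
    direction: str  # left | right
    endpoint_az: float
    peak_velocity: float


def velocity(time, az):
    """Absolute angular speed (deg/s) via central differences.

    Endpoints use one-sided differences.  Requires >= 3 samples for a true
    central estimate (2 are tolerated, returning the single slope).
    Duplicate timestamps raise, since the slope is undefined there.
    """
    time = np.asarray(time, dtype=float)
    az = np.asarray(az, dtype=float)
    if time.size != az.size:
        raise ValueError("time and az must have equal length")
    if time.size < 2:
        return np.zeros_like(az)
    if np.any(np.diff(time) == 0):
        raise ValueError("duplicate timestamps in stream")
    return np.abs(np.gradient(az, time))


def _hemifield(mean_az: float, central_deg: float) -> str:
    if mean_az < -central_deg:
        return "left"
    if mean_az > central_deg:
        return "right"
    return "central"


def detect_fixations(stream: pd.DataFrame,
                     cfg: EventConfig | None = None) -> list[Fixation]:
    """Dispersion-duration fixation detector with velocity check.

    ``stream`` needs ``time`` and ``az_filt`` (falls back to ``az``); an
    ``excluded`` column, if present, breaks events.  Returns possibly empty
    list of non-overlapping fixations in time order.
    """
    cfg = cfg or EventConfig()
    cfg.validate()
    time = np.asarray(stream["time"], dtype=float)
    col = "az_filt" if "az_filt" in stream else "az"
    az = np.asarray(stream[col], dtype=float)
    excluded = (
        np.asarray(stream["excluded"], dtype=bool)
        if "excluded" in stream
        else np.zeros(az.size, dtype=bool)
    )
    fixations: list[Fixation] = []
    for start, stop in _contiguous_segments(~excluded):
        t = time[start:stop]
        a = az[start:stop]
        n = t.size
        if n < 3:
            continue
        dt = float(np.median(np.diff(t)))
        w = max(2, int(np.ceil(cfg.min_fixation_s / dt - 1e-9)))
        if n < w:
            continue
        speed = velocity(t, a)
        slow = speed < cfg.fixation_vmax_deg_s
        i = 0
        while i + w <= n:
            win = a[i:i + w]
            if slow[i:i + w].all() and win.max() - win.min() <= cfg.dispersion_deg:
                lo, hi = win.min(), win.max()
                j = i + w
                while j < n and slow[j]:
                    lo2, hi2 = min(lo, a[j]), max(hi, a[j])
                    if hi2 - lo2 > cfg.dispersion_deg:
                        break
                    lo, hi = lo2, hi2
                    j += 1
                mean_az = float(a[i:j].mean())
                fixations.append(
                    Fixation(
                        t_start=float(t[i]),
                        t_end=float(t[j - 1]),
                        duration=(j - i) * dt,
                        mean_az=mean_az,
                        hemifield=_hemifield(mean_az, cfg.central_deg),
                    )
                )
                i = j
            else:
                i += 1
    return fixations


def detect_saccades(stream: pd.DataFrame,
                    cfg: EventConfig | None = None) -> list[Saccade]:
    """Velocity-threshold saccade detector (runs of speed >= 90 deg/s)."""
    cfg = cfg or EventConfig()
    cfg.validate()
    time = np.asarray(stream["time"], dtype=float)
    col = "az_filt" if "az_filt" in stream else "az"
    az = np.asarray(stream[col], dtype=float)
    excluded = (
        np.asarray(stream["excluded"], dtype=bool)
        if "excluded" in stream
        else np.zeros(az.size, dtype=bool)
    )
    saccades: list[Saccade] = []
    for start, stop in _contiguous_segments(~excluded):
        t = time[start:stop]
        a = az[start:stop]
        if t.size < 3:
            continue
        speed = velocity(t, a)
        fast = speed >= cfg.saccade_vmin_deg_s
        for s0, s1 in _contiguous_segments(fast):
            delta = a[s1 - 1] - a[s0]
            saccades.append(
                Saccade(
                    t_start=float(t[s0]),
                    t_end=float(t[s1 - 1]),
                    amplitude=float(abs(delta)),
                    direction="right" if delta >= 0 else "left",
                    endpoint_az=float(a[s1 - 1]),
                    peak_velocity=float(speed[s0:s1].max()),
                )
            )
    return saccades


def events_to_frame(fixations: list[Fixation],
                    saccades: list[Saccade]) -> pd.DataFrame:
    """Tidy table of all detected events, time-ordered."""
    rows = [
        {
            "type": "fixation",
            "t_start": f.t_start,
            "t_end": f.t_end,
            "duration": f.duration,
            "mean_az": f.mean_az,
            "hemifield": f.hemifield,
            "amplitude": np.nan,
            "direction": "",
            "endpoint_az": np.nan,
        }
        for f in fixations
    ] + [
        {
            "type": "saccade",
            "t_start": s.t_start,
            "t_end": s.t_end,
            "duration": s.t_end - s.t_start,
            "mean_az": np.nan,
            "hemifield": "",
            "amplitude": s.amplitude,
            "direction": s.direction,
            "endpoint_az": s.endpoint_az,
        }
        for s in saccades
    ]
    frame = pd.DataFrame(
        rows,
        columns=["type", "t_start", "t_end", "duration", "mean_az",
                 "hemifield", "amplitude", "direction", "endpoint_az"],
    )
    return frame.sort_values("t_start", kind="stable").reset_index(drop=True)
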