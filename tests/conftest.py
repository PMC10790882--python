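"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(2022)


def make_stream(az, fs: float = 60.0, t0: float = 0.0, **extra) -> pd.DataFrame:
    """Minimal gaze stream from an azimuth array."""
    az = np.asarray(az, dtype=float)
    data = {"time": t0 + np.arange(az.size) / fs, "az": az}
    data.update(extra)
    return pd.DataFrame(data)


def plateau_trace(segments, fs: float = 60.0, transition_speed: float = 300.0):
    """Piecewise-constant azimuth trace: ``segments`` is a list of
    (position_deg, duration_s) plateaus joined by linear ramps at
    ``transition_speed`` deg/s.  Returns (az, plateau_sample_spans)."""
    chunks, spans = [], []
    n_done = 0
    prev = None
    for pos, dur in segments:
        if prev is not None and pos != prev:
            n_ramp = max(1, int(round(abs(pos - prev) / transition_speed * fs)))
            ramp = prev + (pos - prev) * np.arange(1, n_ramp + 1) / (n_ramp + 1)
            chunks.append(ramp)
            n_done += n_ramp
        n = int(round(dur * fs))
        chunks.append(np.full(n, float(pos)))
        spans.append((n_done, n_done + n - 1))
        n_done += n
        prev = pos
    return np.concatenate(chunks), spans


# --- independent brute-force oracles -------------------------------------

def oracle_fixations(time, az, dispersion=2.0, min_dur=0.120, vmax=30.0):
    """All-windows dispersion scan recomputing every window from scratch
    (no incremental state); returns (start, end) sample index pairs."""
    time = np.asarray(time, float)
    az = np.asarray(az, float)
    n = az.size
    if n < 3:
        return []
    dt = float(np.median(np.diff(time)))
    speed = np.abs(np.gradient(az, time))
    w = max(2, int(np.ceil(min_dur / dt - 1e-9)))
    out = []
    i = 0
    while i + w <= n:
        window = az[i:i + w]
        if window.max() - window.min() <= dispersion and \
                (speed[i:i + w] < vmax).all():
            j = i + w
            while j < n and speed[j] < vmax and \
                    az[i:j + 1].max() - az[i:j + 1].min() <= dispersion:
                j += 1
            out.append((i, j - 1))
            i = j
        else:
            i += 1
    return out


def oracle_saccades(time, az, vmin=90.0):
    """Run-length scan over the velocity series using plain iteration."""
    time = np.asarray(time, float)
    az = np.asarray(az, float)
    if az.size < 3:
        return []
    speed = np.abs(np.gradient(az, time))
    out = []
    start = None
    for i, fast in enumerate(speed >= vmin):
        if fast and start is None:
            start = i
        elif not fast and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, az.size - 1))
    return out


def random_event_trace(rng, fs: float = 60.0, noise_sd: float = 0.2):
    """Random plateaus joined by random-speed ramps, for oracle tests."""
    n_plat = int(rng.integers(2, 6))
    segments = [(float(rng.uniform(-60, 60)), float(rng.uniform(0.15, 0.6)))
                for _ in range(n_plat)]
    az, _ = plateau_trace(segments, fs=fs,
                          transition_speed=float(rng.uniform(150, 500)))
    if noise_sd > 0:
        az = az + rng.normal(0.0, noise_sd, az.size)
    return az
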