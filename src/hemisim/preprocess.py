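"""Cleaning of raw 60 Hz gaze streams before event detection.

The pipeline order is fixed: (1) replace invalid eye samples by the more
stable head-pose-derived direction, (2) flag samples to be excluded from all
gaze analyses (blinks, mirror and media-system glances, other non-driving
areas) without closing the time gaps they leave, (3) low-pass filter the
horizontal gaze channel at 10 Hz per contiguous unexcluded segment.

The low-pass is applied zero-phase with the exact squared Butterworth
magnitude |H(f)|^2 = 1 / (1 + (f/fc)^(2n)) realised in the frequency domain
on reflection-padded segments.  This matches the magnitude response of an
ideal forward-backward Butterworth pass without the bilinear frequency
warping a discrete-time design would introduce near Nyquist, and keeps
fixation onsets unbiased (no phase lag).  Offline analysis tolerates the
non-causality.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .config import FilterConfig

__all__ = [
    "DEFAULT_EXCLUDED_AOIS",
    "merge_head_fallback",
    "exclude_regions",
    "lowpass",
    "butterworth_magnitude_filter",
    "preprocess",
]

DEFAULT_EXCLUDED_AOIS = frozenset({"blink", "mirror", "media", "other"})


def merge_head_fallback(stream: pd.DataFrame) -> pd.DataFrame:
    """Fill invalid eye samples from the head-based gaze direction.

    Substituted samples carry ``source='head'``.  Invalid samples with no
    head direction available carry the last usable azimuth forward and are
    marked ``source='held'`` (with a warning).  The substitution count is
    stored in ``result.attrs['n_head_substituted']``.
    """
    out = stream.copy()
    n = len(out)
    valid = (
        np.asarray(out["valid"], dtype=bool)
        if "valid" in out
        else np.ones(n, dtype=bool)
    )
    valid = valid & np.isfinite(np.asarray(out["az"], dtype=float))
    az = np.asarray(out["az"], dtype=float)
    head = (
        np.asarray(out["head_az"], dtype=float)
        if "head_az" in out
        else np.full(n, np.nan)
    )
    source = np.where(valid, "eye", "head").astype(object)
    need = ~valid
    have_head = np.isfinite(head)
    az = np.where(need & have_head, head, az)
    n_head = int(np.sum(need & have_head))

    missing = need & ~have_head
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} invalid samples had no head fallback; "
            "carrying last azimuth"
        )
        source[missing] = "held"
        filled = pd.Series(np.where(missing, np.nan, az)).ffill().bfill().to_numpy()
        az = np.where(missing, filled, az)
    az = np.nan_to_num(az, nan=0.0)

    out["az"] = az
    out["source"] = source
    out.attrs["n_head_substituted"] = n_head
    out.attrs["n_held"] = int(missing.sum())
    return out


def exclude_regions(stream: pd.DataFrame,
                    excluded_aois=DEFAULT_EXCLUDED_AOIS) -> pd.DataFrame:
    """Flag samples whose area-of-interest label is excluded from analysis.

    Flagged samples are dropped from event detection and all gaze statistics
    but still advance time: gaps are not closed and no gaze positions are
    interpolated into them.
    """
    out = stream.copy()
    if "aoi" not in out or out["aoi"].isna().all():
        warnings.warn("no AOI labels present; nothing excluded")
        out["excluded"] = False
        return out
    aoi = out["aoi"].astype(object)
    out["excluded"] = aoi.isin(set(excluded_aois)).to_numpy()
    out.attrs["n_excluded"] = int(out["excluded"].sum())
    return out


def butterworth_magnitude_filter(x: np.ndarray, fs: float, cutoff: float,
                                 order: int = 2) -> np.ndarray:
    """Zero-phase low-pass with gain 1/(1 + (f/fc)^(2*order)).

    The gain is the squared magnitude of an order-``order`` Butterworth,
    i.e. the response of one forward and one backward pass.  Applied via the
    real FFT on a reflection-padded copy to suppress edge transients; DC
    gain is exactly 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return x.copy()
    pad = min(n - 1, max(8, int(round(3 * fs / cutoff))))
    left = x[pad:0:-1]
    right = x[-2:-2 - pad:-1]
    xp = np.concatenate([left, x, right])
    freqs = np.fft.rfftfreq(xp.size, d=1.0 / fs)
    gain = 1.0 / (1.0 + (freqs / cutoff) ** (2 * order))
    y = np.fft.irfft(np.fft.rfft(xp) * gain, xp.size)
    return y[pad:pad + n]


def _contiguous_segments(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, stops)


def lowpass(stream: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Low-pass the azimuth channel per contiguous unexcluded segment.

    Adds an ``az_filt`` column.  Segments shorter than
    ``cfg.min_segment_samples`` are passed through unfiltered; excluded
    samples keep their raw azimuth.  With ``zero_phase=False`` a causal
    discrete Butterworth (scipy) is used instead.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    out = stream.copy()
    az = np.asarray(out["az"], dtype=float)
    excluded = (
        np.asarray(out["excluded"], dtype=bool)
        if "excluded" in out
        else np.zeros(az.size, dtype=bool)
    )
    filt = az.copy()
    for start, stop in _contiguous_segments(~excluded):
        seg = az[start:stop]
        if seg.size < cfg.min_segment_samples:
            continue
        if cfg.zero_phase:
            filt[start:stop] = butterworth_magnitude_filter(
                seg, cfg.sample_rate_hz, cfg.cutoff_hz, cfg.order
            )
        else:
            sos = signal.butter(
                cfg.order, cfg.cutoff_hz, fs=cfg.sample_rate_hz, output="sos"
            )
            filt[start:stop] = signal.sosfilt(sos, seg)
    out["az_filt"] = filt
    return out


def preprocess(stream: pd.DataFrame, filter_cfg: FilterConfig | None = None,
               excluded_aois=DEFAULT_EXCLUDED_AOIS) -> pd.DataFrame:
    """Full cleaning pipeline: head fallback -> AOI exclusion -> low-pass."""
    return lowpass(
        exclude_regions(merge_head_fallback(stream), excluded_aois), filter_cfg
    )
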