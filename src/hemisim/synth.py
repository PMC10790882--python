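"""Synthetic study generator: gaze scanpaths, driving traces, full designs.

Emulates a 15-subject within-subject study with three vision conditions
(NV = normal vision, LHH/RHH = simulated left/right homonymous hemianopia)
crossed with three intersection maneuvers (SCI straight, LTI left turn,
RTI right turn).  Every generated scenario carries planted ground truth —
event lists, first-peripheral-scan sides, missing-large-scan flags, lane
crossings, deceleration-window bounds — so each pipeline stage can be
validated without recorded data.

Scanpaths alternate fixations (lognormal durations) and saccades (raised-
cosine transitions whose peak velocity sits well above the 90 deg/s
detection threshold).  Fixation positions follow a mean-reverting random
walk around the condition's gaze bias, with per-scenario peripheral
excursions (staircases of ordinary-amplitude saccades out to >=50 deg and
back) drawn with condition-dependent probabilities per side.  Blinks are
modelled as brief occlusions between events, a fraction of samples drop out
(eye-tracker signal loss, with a 2 Hz-smoothed head-gaze channel as
fallback), and occasional mirror glances exercise the AOI exclusion.

Detector-native planting.  A 60 Hz sampled, 10 Hz low-passed saccade is an
attenuated version of the planted step: threshold-crossing endpoints read
only part of the displacement, and the velocity check shaves samples off
the flanking fixations.  Both distortions are deterministic properties of
the measurement chain, so the generator calibrates them once (by pushing
its own transition template through the filter and detector) and plants
inflated position steps / extended plateaus such that the *expected
detector reading* equals the drawn parameter.  Planted amplitudes and
durations therefore denote detector-level quantities; the calibration is
computed at run time from the filter and threshold settings, not fitted.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import EventConfig, FilterConfig
from .events import detect_fixations, detect_saccades
from .preprocess import butterworth_magnitude_filter

__all__ = [
    "ConditionProfile",
    "DriveProfile",
    "DEFAULT_PROFILES",
    "DEFAULT_DRIVE",
    "noise_free",
    "generate_scanpath",
    "generate_drive",
    "generate_study",
    "ScanpathResult",
    "DriveResult",
]

# |azimuth| bands kept free of fixation positions so that the 30 and 45 deg
# scan criteria are never decided by sub-degree noise
_GUARD_BANDS = ((27.0, 33.0), (42.0, 48.0))
_EXCURSION_ZONE = 50.0
_POS_LIMIT = 75.0
_MIN_AMP = 8.0


@dataclass
class ConditionProfile:
    """Scanning statistics of one vision condition.

    Defaults follow the directions reported for simulated hemianopia
    (longer fixations and smaller saccadic amplitudes under LHH, rightward
    gaze bias under RHH, more missing large scans under LHH); magnitudes
    are free parameters of the generator.
    """

    name: str = "NV"
    fix_dur_mean: float = 0.26   # s
    fix_dur_sd: float = 0.065    # s
    sacc_amp_mean: float = 30.0  # deg
    sacc_amp_sd: float = 9.0     # deg
    gaze_bias: float = -2.5      # deg, mean horizontal eccentricity
    p_large_scan_left: float = 0.886
    p_large_scan_right: float = 0.75
    blink_rate_per_min: float = 10.0
    dropout_rate: float = 0.02
    mirror_rate_per_min: float = 2.0
    noise_sd: float = 0.3        # deg

    def validate(self) -> None:
        if self.fix_dur_mean < 0.135:
            raise ValueError(
                "mean fixation duration below the detection minimum "
                "(need > 0.135 s)"
            )
        if self.fix_dur_sd < 0 or self.sacc_amp_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.sacc_amp_mean < _MIN_AMP:
            raise ValueError(f"mean saccade amplitude must be >= {_MIN_AMP} deg")
        for p in (self.p_large_scan_left, self.p_large_scan_right):
            if not 0 <= p <= 1:
                raise ValueError("scan probabilities must be in [0, 1]")
        if self.dropout_rate < 0 or self.dropout_rate > 0.5:
            raise ValueError("dropout_rate must be in [0, 0.5]")


@dataclass
class DriveProfile:
    """Longitudinal and lateral driving behavior of one approach."""

    approach_speed_kmh: float = 50.0
    start_dist_m: float = 150.0
    brake_onset_dist_m: object = "sample"  # float | None (never brakes) | "sample"
    brake_dist_range: tuple[float, float] = (25.0, 95.0)
    p_brake_beyond_100: float = 0.05
    p_no_brake: float = 0.05
    end_speed_kmh: float = 7.0
    lane_offset_mean_cm: float = -15.0
    lane_ar1_phi: float = 0.999
    lane_noise_sd_cm: float = 0.55
    crossing_boundary_cm: float = 85.0
    p_lane_crossing: float = 0.045
    cross_traffic_period_s: float = 9.0  # scene metadata, not simulated

    def validate(self) -> None:
        if not abs(self.lane_ar1_phi) < 1:
            raise ValueError("|lane_ar1_phi| must be < 1")
        if self.approach_speed_kmh <= 0 or self.end_speed_kmh <= 0:
            raise ValueError("speeds must be positive")


DEFAULT_PROFILES = {
    "NV": ConditionProfile("NV", 0.26, 0.065, 30.0, 9.0, -2.5, 0.886, 0.750),
    "LHH": ConditionProfile("LHH", 0.335, 0.080, 19.6, 6.0, -1.9, 0.682, 0.568),
    "RHH": ConditionProfile("RHH", 0.31, 0.075, 28.0, 8.4, 3.4, 0.841, 0.705),
}
DEFAULT_DRIVE = DriveProfile()


def noise_free(profile: ConditionProfile) -> ConditionProfile:
    """Copy of a profile with all corruption channels switched off."""
    return replace(profile, noise_sd=0.0, blink_rate_per_min=0.0,
                   dropout_rate=0.0, mirror_rate_per_min=0.0)


@dataclass
class ScanpathResult:
    stream: pd.DataFrame
    events: pd.DataFrame
    truth: dict
    end_pos: float
    delta: float = 0.0  # recentering shift applied to the whole trace


@dataclass
class DriveResult:
    stream: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# saccade kinematics and detector calibration


def _transition_samples(amp: float, fs: float) -> np.ndarray:
    """Raised-cosine transition fractions (relative displacement per sample),
    peak velocity well above the 90 deg/s saccade threshold."""
    v_peak = max(250.0, 30.0 * amp ** 0.75)
    t_total = amp * np.pi / (2.0 * v_peak)
    n = max(1, int(round(t_total * fs)))
    phase = np.arange(1, n + 1) / (n + 1)
    return (1.0 - np.cos(np.pi * phase)) / 2.0


@functools.lru_cache(maxsize=8)
def _detector_calibration(fs: float = 60.0, cutoff: float = 10.0,
                          order: int = 2) -> tuple:
    """Measure the detector's response to the generator's own transitions.

    For a grid of planted step sizes, a template (plateau, transition,
    plateau) is filtered and run through the event detectors, yielding the
    expected measured amplitude and the per-side fixation-sample deficit.
    Returns (planted_grid, measured_amps, erosion_samples_per_side).
    """
    cfg = EventConfig()
    n_plateau = 40
    grid = np.array([3.0, 5.0, 8.0, 10.0, 12.0, 14.0, 17.0, 20.0, 24.0, 28.0,
                     34.0, 40.0, 48.0, 56.0, 65.0, 75.0, 85.0, 95.0, 110.0])
    measured, erosion = [], []
    for amp in grid:
        frac = _transition_samples(amp, fs)
        az = np.concatenate(
            [np.zeros(n_plateau), amp * frac, np.full(n_plateau, amp)]
        )
        t = np.arange(az.size) / fs
        stream = pd.DataFrame({
            "time": t,
            "az": az,
            "az_filt": butterworth_magnitude_filter(az, fs, cutoff, order),
        })
        sacc = detect_saccades(stream, cfg)
        measured.append(max((s.amplitude for s in sacc), default=0.0))
        fix = detect_fixations(stream, cfg)
        detected = sum(int(round(f.duration * fs)) for f in fix)
        erosion.append(max(0.0, (2 * n_plateau - detected) / 2.0))
    measured = np.maximum.accumulate(np.asarray(measured))  # monotone for inversion
    return grid, measured, np.asarray(erosion)


def _plant_step(target_amp: float, fs: float) -> float:
    """Position step whose expected detector reading is ``target_amp``."""
    grid, measured, _ = _detector_calibration(fs)
    return float(np.interp(target_amp, measured, grid))


def _expected_reading(pos_step: float, fs: float) -> float:
    grid, measured, _ = _detector_calibration(fs)
    return float(np.interp(abs(pos_step), grid, measured))


def _erosion_per_side(pos_step: float, fs: float) -> float:
    grid, _, erosion = _detector_calibration(fs)
    return float(np.interp(abs(pos_step), grid, erosion))


_shave_cache: dict[tuple, float] = {}


def _corruption_shave(profile: ConditionProfile, fs: float) -> float:
    """Expected extra fixation-sample loss caused by the stochastic
    corruption channels (noise, dropouts with head-gaze substitution).

    Dropout samples substituted by the lagging head channel perturb fixation
    edges after filtering, shaving a fraction of a sample off the average
    detected duration.  The effect is measured once per profile by running
    the generator's own output (with compensation disabled, fixed internal
    seeds) through the detection chain; the result — samples per fixation —
    is deterministic for a given profile and rate.
    """
    if profile.noise_sd == 0 and profile.dropout_rate == 0:
        return 0.0
    key = (round(profile.fix_dur_mean, 4), round(profile.fix_dur_sd, 4),
           round(profile.sacc_amp_mean, 2), round(profile.sacc_amp_sd, 2),
           round(profile.gaze_bias, 2), round(profile.noise_sd, 3),
           round(profile.dropout_rate, 4),
           round(profile.blink_rate_per_min, 2),
           round(profile.mirror_rate_per_min, 2), fs)
    if key not in _shave_cache:
        _shave_cache[key] = 0.0  # disables compensation for the probe runs
        from .preprocess import preprocess as _run_preprocess

        diffs: list[float] = []
        for probe_seed in (911, 912, 913):
            r = generate_scanpath(profile, 30.0, seed=probe_seed, fs=fs)
            fx = detect_fixations(_run_preprocess(r.stream))
            fev = r.events[(r.events["type"] == "fixation")
                           & (r.events["aoi"] == "front")]
            for f in fx:
                near = fev[(fev["t_start"] - f.t_start).abs() < 0.08]
                if len(near):
                    diffs.append(f.duration - float(near["duration"].iloc[0]))
        shave = -float(np.mean(diffs)) * fs if diffs else 0.0
        _shave_cache[key] = max(0.0, shave)
    return _shave_cache[key]


# ---------------------------------------------------------------------------
# scanpath generation


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _avoid_bands(pos: float, prev: float) -> float:
    a = abs(pos)
    for lo, hi in _GUARD_BANDS:
        if lo <= a <= hi:
            outward = abs(pos) >= abs(prev)
            a = hi + 0.6 if outward else lo - 0.6
            return float(np.copysign(a, pos)) if pos != 0 else a
    return pos


@functools.lru_cache(maxsize=64)
def _truncnorm_loc(mean: float, sd: float, lower: float = _MIN_AMP) -> float:
    """Location of a lower-truncated normal whose mean equals ``mean``.

    Saccade amplitudes are truncated at the smallest displacement the
    detector resolves reliably; without re-centering, truncation would bias
    the realised mean above the profile parameter.
    """
    from scipy.stats import truncnorm

    loc = mean
    for _ in range(50):
        a = (lower - loc) / sd
        m = float(truncnorm.mean(a, np.inf, loc=loc, scale=sd))
        if abs(m - mean) < 1e-10:
            break
        loc -= m - mean
    return loc


def _draw_amp(rng: np.random.Generator, profile: ConditionProfile) -> float:
    if profile.sacc_amp_sd == 0:
        return max(_MIN_AMP, profile.sacc_amp_mean)
    loc = _truncnorm_loc(profile.sacc_amp_mean, profile.sacc_amp_sd)
    for _ in range(256):
        a = rng.normal(loc, profile.sacc_amp_sd)
        if a >= _MIN_AMP:
            return float(a)
    return _MIN_AMP


def generate_scanpath(profile: ConditionProfile, duration: float,
                      seed: int | None = None, *,
                      rng: np.random.Generator | None = None,
                      fs: float = 60.0, t0: float = 0.0,
                      start_pos: float | None = None) -> ScanpathResult:
    """Generate one gaze stream with planted events and scan ground truth.

    The stream covers ``duration`` seconds at ``fs`` Hz starting at ``t0``.
    Identical seeds give byte-identical output.  ``truth`` carries
    ``first_scan_30/45`` (side of the earliest non-excluded clean sample at
    or beyond the threshold), ``missing_left/right`` (45 deg criterion),
    and the planted event counts.
    """
    profile.validate()
    if duration < 1.0:
        raise ValueError("duration must be >= 1 s")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_total = int(round(duration * fs))
    mu, sigma = _lognormal_params(profile.fix_dur_mean, profile.fix_dur_sd)
    per_boundary = (profile.fix_dur_mean + 0.08) / 60.0  # events per boundary per unit rate

    # schedule excursions: Bernoulli per side, trigger times in the window
    excursions = []
    if rng.random() < profile.p_large_scan_left:
        excursions.append([-1.0, rng.uniform(0.05, 0.60) * duration])
    if rng.random() < profile.p_large_scan_right:
        excursions.append([+1.0, rng.uniform(0.05, 0.60) * duration])
    rng.shuffle(excursions)
    excursions.sort(key=lambda e: e[1])

    initial_fixation = start_pos is None
    if initial_fixation:
        pos = profile.gaze_bias + rng.normal(0.0, 10.0)
        pos = float(np.clip(pos, -25.0, 25.0))
        pos = _avoid_bands(pos, 0.0)
    else:
        # stream opens with a transition away from the handed-over position,
        # so the first planted fixation's onset lies inside this stream
        pos = float(start_pos)

    chunks: list[np.ndarray] = []
    aoi_chunks: list[np.ndarray] = []
    fix_events: list[dict] = []
    sacc_events: list[dict] = []
    n_done = 0
    staircase_sign = 0.0

    def draw_fixation(position: float) -> tuple[int, str]:
        dur = float(rng.lognormal(mu, sigma)) if sigma > 0 else profile.fix_dur_mean
        n = max(9, int(round(dur * fs)))
        label = "front"
        if abs(position) < 25.0 and profile.mirror_rate_per_min > 0:
            if rng.random() < profile.mirror_rate_per_min * per_boundary:
                label = "mirror"
        return n, label

    def emit_fixation(position: float, n: int, label: str) -> None:
        nonlocal n_done
        chunks.append(np.full(n, position))
        aoi_chunks.append(np.full(n, label, dtype=object))
        fix_events.append({
            "type": "fixation", "i_start": n_done, "n": n,
            "duration": n / fs, "pos": position, "aoi": label,
        })
        n_done += n

    def emit_pad(position: float, n: int) -> None:
        # plateau extension compensating detector-side sample erosion;
        # belongs to no planted event
        nonlocal n_done
        if n <= 0:
            return
        chunks.append(np.full(n, position))
        aoi_chunks.append(np.full(n, "front", dtype=object))
        n_done += n

    def emit_transition(p0: float, p1: float) -> None:
        nonlocal n_done
        frac = _transition_samples(abs(p1 - p0), fs)
        seg = p0 + (p1 - p0) * frac
        chunks.append(seg)
        aoi_chunks.append(np.full(seg.size, "front", dtype=object))
        sacc_events.append({
            "type": "saccade", "i_start": n_done, "n": seg.size,
            "amplitude": _expected_reading(p1 - p0, fs),
            "direction": "right" if p1 >= p0 else "left",
            "endpoint": p1,
        })
        n_done += seg.size

    def emit_blink(position: float, n: int) -> None:
        nonlocal n_done
        chunks.append(np.full(n, position))
        aoi_chunks.append(np.full(n, "blink", dtype=object))
        n_done += n

    def rounded(x: float) -> int:
        return int(x) + int(rng.random() < (x - int(x)))

    shave_per_side = _corruption_shave(profile, fs) / 2.0

    if initial_fixation:
        n0, label0 = draw_fixation(pos)
        emit_fixation(pos, n0, label0)
    while n_done < n_total:
        # blink between events?
        blink_n = 0
        if profile.blink_rate_per_min > 0 and \
                rng.random() < profile.blink_rate_per_min * per_boundary:
            blink_n = int(rng.integers(9, 19))
        # choose next position
        if staircase_sign == 0.0 and excursions and \
                n_done / fs >= excursions[0][1]:
            staircase_sign = excursions[0][0]
            excursions.pop(0)
        if staircase_sign != 0.0 and np.sign(pos) == staircase_sign \
                and abs(pos) >= _EXCURSION_ZONE:
            staircase_sign = 0.0  # excursion completed
        step = _plant_step(_draw_amp(rng, profile), fs)
        if staircase_sign != 0.0:
            cand = pos + staircase_sign * step
            if abs(cand) > _POS_LIMIT:
                cand = float(np.copysign(_POS_LIMIT, cand))
        else:
            p_right = float(np.clip(0.5 - (pos - profile.gaze_bias) / 120.0,
                                    0.05, 0.95))
            sign = 1.0 if rng.random() < p_right else -1.0
            cand = pos + sign * step
            if abs(cand) > _POS_LIMIT:
                cand = pos - sign * step
        cand = _avoid_bands(cand, pos)
        ext = _erosion_per_side(cand - pos, fs) + shave_per_side
        fix_n, fix_label = draw_fixation(cand)
        if blink_n:
            emit_blink(pos, blink_n)
        emit_pad(pos, rounded(ext))
        emit_transition(pos, cand)
        emit_pad(cand, rounded(ext))
        pos = cand
        # the final cycle may overrun the nominal duration: cropping it would
        # under-sample long fixations (length-biased truncation), so the
        # stream is allowed to end slightly late instead
        emit_fixation(pos, fix_n, fix_label)

    az_clean = np.concatenate(chunks)
    aoi = np.concatenate(aoi_chunks)
    n_actual = az_clean.size
    # ground truth refers to the nominal window [0, duration]: the samples a
    # consumer slicing at t0 + duration would see
    n_prefix = min(n_actual, int(np.floor(duration * fs + 1e-6)) + 1)
    front = aoi == "front"

    # gaze_bias is the mean eccentricity shift: recenter the realised trace
    # so the window-mean of analysed samples equals the parameter exactly
    # (the excursion machinery would otherwise offset it stochastically)
    delta = 0.0
    if front[:n_prefix].any():
        delta = profile.gaze_bias - float(az_clean[:n_prefix][front[:n_prefix]].mean())
    az_clean = az_clean + delta
    az = az_clean

    # Scan ground truth is defined on the noise-free *filtered* trace: the
    # pipeline applies its eccentricity thresholds after the 10 Hz low-pass,
    # whose slight overshoot near large saccades is part of the measurement.
    # When the stream continues an earlier position, that context is
    # prepended for filtering so edge transients match downstream filtering.
    fcfg = FilterConfig()
    if initial_fixation:
        ctx = np.empty(0)
    else:
        ctx = np.full(32, float(start_pos) + delta)
    filt_truth = butterworth_magnitude_filter(
        np.concatenate([ctx, az_clean]), fs, fcfg.cutoff_hz, fcfg.order
    )[ctx.size:]
    truth = _scan_truth(filt_truth[:n_prefix], front[:n_prefix], fs)
    events = _materialize_events(fix_events, sacc_events, n_actual, t0, fs,
                                 delta)
    in_window = events["t_start"] <= t0 + (n_prefix - 1) / fs + 1e-9
    truth.update({
        "n_fixations": int(((events["type"] == "fixation") & in_window).sum()),
        "n_fixations_front": int(((events["type"] == "fixation") & in_window
                                  & (events["aoi"] == "front")).sum()),
        "n_saccades": int(((events["type"] == "saccade") & in_window).sum()),
    })

    # corruption: position noise, dropouts, head channel
    noisy = az + rng.normal(0.0, profile.noise_sd, n_actual) \
        if profile.noise_sd > 0 else az.copy()
    valid = aoi != "blink"
    if profile.dropout_rate > 0:
        # tracker signal loss concentrates during large gaze/head movements;
        # weight per-sample dropout odds by local angular speed while keeping
        # the overall expected dropout fraction at profile.dropout_rate
        speed_w = np.abs(np.gradient(az_clean)) + 0.05
        p_drop = profile.dropout_rate * n_actual * speed_w / speed_w.sum()
        drop = rng.random(n_actual) < np.clip(p_drop, 0.0, 0.9)
        valid = valid & ~drop
    noisy = np.where(valid, noisy, np.nan)
    head = butterworth_magnitude_filter(az_clean, fs, 2.0, 2)
    if profile.noise_sd > 0:
        head = head + rng.normal(0.0, profile.noise_sd, n_actual)
    el = butterworth_magnitude_filter(rng.normal(-3.0, 4.0, n_actual), fs, 1.0, 2)

    stream = pd.DataFrame({
        "time": t0 + np.arange(n_actual) / fs,
        "az": noisy,
        "el": el,
        "valid": valid,
        "head_az": head,
        "aoi": aoi,
    })
    return ScanpathResult(stream=stream, events=events, truth=truth,
                          end_pos=float(az_clean[-1]), delta=delta)


def _scan_truth(az_clean: np.ndarray, front: np.ndarray, fs: float) -> dict:
    truth: dict = {}
    usable = az_clean[front]
    for name, thr in (("first_scan_30", 30.0), ("first_scan_45", 45.0)):
        idx = np.nonzero(front & (np.abs(az_clean) >= thr))[0]
        truth[name] = ("none" if idx.size == 0
                       else ("left" if az_clean[idx[0]] < 0 else "right"))
    truth["missing_left"] = bool(usable.size == 0 or usable.min() > -45.0)
    truth["missing_right"] = bool(usable.size == 0 or usable.max() < 45.0)
    return truth


def _materialize_events(fix_events: list[dict], sacc_events: list[dict],
                        n_total: int, t0: float, fs: float,
                        delta: float = 0.0) -> pd.DataFrame:
    rows = []
    for ev in fix_events:
        if ev["i_start"] + ev["n"] > n_total:
            continue
        rows.append({
            "type": "fixation",
            "t_start": t0 + ev["i_start"] / fs,
            "duration": ev["duration"],
            "pos": ev["pos"] + delta,
            "amplitude": np.nan,
            "direction": "",
            "aoi": ev["aoi"],
        })
    for ev in sacc_events:
        if ev["i_start"] + ev["n"] > n_total:
            continue
        rows.append({
            "type": "saccade",
            "t_start": t0 + ev["i_start"] / fs,
            "duration": ev["n"] / fs,
            "pos": ev["endpoint"] + delta,
            "amplitude": ev["amplitude"],
            "direction": ev["direction"],
            "aoi": "front",
        })
    frame = pd.DataFrame(
        rows, columns=["type", "t_start", "duration", "pos", "amplitude",
                       "direction", "aoi"],
    )
    return frame.sort_values("t_start", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# driving traces


def generate_drive(profile: DriveProfile | None = None,
                   seed: int | None = None, *,
                   rng: np.random.Generator | None = None,
                   fs: float = 240.0) -> DriveResult:
    """Simulate one intersection approach at 240 Hz.

    Constant approach speed until the brake onset distance, then constant
    deceleration down to the crossing speed; the lane-position offset is an
    AR(1) process around the profile mean with optional planted boundary
    crossings (smooth excursions beyond the crossing boundary).  The truth
    dict holds the deceleration-window bounds, its trigger, the brake onset
    distance and the planted crossing count.
    """
    profile = profile or DEFAULT_DRIVE
    profile.validate()
    rng = rng if rng is not None else np.random.default_rng(seed)
    v0 = profile.approach_speed_kmh / 3.6
    vf = profile.end_speed_kmh / 3.6

    onset = profile.brake_onset_dist_m
    if isinstance(onset, str):  # "sample"
        u = rng.random()
        if u < profile.p_no_brake:
            onset = None
        elif u < profile.p_no_brake + profile.p_brake_beyond_100:
            onset = float(rng.uniform(102.0, 118.0))
        else:
            onset = float(rng.uniform(*profile.brake_dist_range))
    if onset is not None and onset > profile.start_dist_m:
        raise ValueError("brake onset beyond the initial distance")

    dt = 1.0 / fs
    decel = (v0 ** 2 - vf ** 2) / (2.0 * onset) if onset else 0.0
    dist_list, speed_list, brake_list = [], [], []
    dist, v, braking = profile.start_dist_m, v0, False
    while dist > 0:
        if onset is not None and dist <= onset:
            braking = True
        if braking:
            v = max(vf, v - decel * dt)
        dist_list.append(dist)
        speed_list.append(v)
        brake_list.append(braking)
        dist -= v * dt
    dist_arr = np.asarray(dist_list)
    dist_arr[-1] = 0.0  # the zebra crossing is reached on the final sample
    n = dist_arr.size
    time = np.arange(n) * dt

    search = np.nonzero(np.asarray(brake_list) & (dist_arr <= 100.0))[0]
    if search.size:
        i0, trigger = int(search[0]), "brake"
    else:
        i0 = int(np.nonzero(dist_arr <= 41.76)[0][0])
        trigger = "fallback"

    # lane offset: stationary AR(1) + optional planted crossing excursions,
    # placed inside the deceleration window where lane metrics are computed
    phi, sd = profile.lane_ar1_phi, profile.lane_noise_sd_cm
    if sd > 0:
        eps = rng.normal(0.0, sd, n)
        ar = np.empty(n)
        ar[0] = rng.normal(0.0, sd / np.sqrt(1 - phi ** 2))
        for i in range(1, n):
            ar[i] = phi * ar[i - 1] + eps[i]
    else:
        ar = np.zeros(n)
    lane = profile.lane_offset_mean_cm + ar
    n_cross = int(rng.random() < profile.p_lane_crossing)
    width = int(round(1.2 * fs))
    if n - i0 <= width + 4:
        n_cross = 0  # window too short for a clean excursion
    for _ in range(n_cross):
        center = int(rng.uniform(i0 + width // 2 + 2,
                                 n - width // 2 - 2))
        lo, hi = center - width // 2, center + width // 2
        side = 1.0 if rng.random() < 0.5 else -1.0
        peak = side * (profile.crossing_boundary_cm + 20.0) \
            - profile.lane_offset_mean_cm
        ramp = 0.5 * (1 - np.cos(2 * np.pi * np.arange(hi - lo) / (hi - lo)))
        lane[lo:hi] += peak * ramp

    stream = pd.DataFrame({
        "time": time,
        "dist": dist_arr,
        "lane_offset": lane,
        "brake": np.asarray(brake_list, dtype=bool),
        "speed_kmh": np.asarray(speed_list) * 3.6,
    })
    truth = {
        "t_start": float(time[i0]),
        "t_end": float(time[-1]),
        "trigger": trigger,
        "brake_onset_dist": onset,
        "lane_crossings": n_cross,
    }
    return DriveResult(stream=stream, truth=truth)


# ---------------------------------------------------------------------------
# full study


def _steady_gaze(pos: float, duration: float, profile: ConditionProfile,
                 rng: np.random.Generator, fs: float,
                 t0: float) -> pd.DataFrame | None:
    """Stationary gaze segment preceding the analysis window (no planted
    events); ends one sample before ``t0 + duration``."""
    n = int(round(duration * fs))
    if n < 1:
        return None
    az = np.full(n, pos)
    noisy = az + rng.normal(0.0, profile.noise_sd, n) if profile.noise_sd > 0 \
        else az.copy()
    head = az + (rng.normal(0.0, profile.noise_sd, n)
                 if profile.noise_sd > 0 else 0.0)
    el = butterworth_magnitude_filter(rng.normal(-3.0, 4.0, n), fs, 1.0, 2)
    return pd.DataFrame({
        "time": t0 + np.arange(n) / fs,
        "az": noisy,
        "el": el,
        "valid": np.ones(n, dtype=bool),
        "head_az": head,
        "aoi": np.full(n, "front", dtype=object),
    })


def generate_study(n_subjects: int = 15,
                   profiles: dict[str, ConditionProfile] | None = None,
                   drive_profile: DriveProfile | None = None,
                   master_seed: int = 0,
                   intersections: tuple[str, ...] = ("SCI", "LTI", "RTI"),
                   clean: bool = False,
                   gaze_fs: float = 60.0, drive_fs: float = 240.0) -> dict:
    """Generate the full subject x condition x intersection design.

    Returns ``{"scenarios": [...], "manifest": DataFrame}`` where each
    scenario dict carries the gaze and drive streams, planted events and
    ground truth.  Per-scenario seeds derive deterministically from
    ``master_seed``; ``clean=True`` switches every corruption channel off
    (the noise-free setting in which categorical truths are recovered
    exactly).
    """
    profiles = dict(profiles or DEFAULT_PROFILES)
    drive_profile = drive_profile or DEFAULT_DRIVE
    if clean:
        profiles = {k: noise_free(v) for k, v in profiles.items()}
        drive_profile = replace(drive_profile, lane_noise_sd_cm=0.0)
    root = np.random.SeedSequence(master_seed)
    scenarios = []
    manifest_rows = []
    n_cells = n_subjects * len(profiles) * len(intersections)
    seeds = root.spawn(n_cells)
    cell = 0
    for s in range(1, n_subjects + 1):
        for cond, profile in profiles.items():
            for intersection in intersections:
                rng = np.random.default_rng(seeds[cell])
                cell += 1
                drive = generate_drive(drive_profile, rng=rng, fs=drive_fs)
                t_start, t_end = drive.truth["t_start"], drive.truth["t_end"]
                preamble_dur = min(t_start, 3.0)
                window_dur = t_end - t_start
                # preamble: steady straight-ahead-ish gaze before the brake
                # point, outside the analysis window
                start_pos = profile.gaze_bias + rng.normal(0.0, 8.0)
                start_pos = _avoid_bands(float(np.clip(start_pos, -25, 25)), 0.0)
                pre_stream = _steady_gaze(start_pos, preamble_dur, profile,
                                          rng, gaze_fs,
                                          t0=t_start - preamble_dur)
                scan = generate_scanpath(profile, window_dur, rng=rng,
                                         fs=gaze_fs, t0=t_start,
                                         start_pos=start_pos)
                if pre_stream is not None and scan.delta != 0.0:
                    # keep the handover continuous under trace recentering
                    pre_stream = pre_stream.assign(
                        az=pre_stream["az"] + scan.delta,
                        head_az=pre_stream["head_az"] + scan.delta,
                    )
                gaze = (pd.concat([pre_stream, scan.stream],
                                  ignore_index=True)
                        if pre_stream is not None else scan.stream)
                truth = {
                    "subject": f"S{s:02d}", "condition": cond,
                    "intersection": intersection,
                    **drive.truth, **scan.truth,
                }
                scenarios.append({
                    "subject": f"S{s:02d}", "condition": cond,
                    "intersection": intersection,
                    "gaze": gaze, "drive": drive.stream,
                    "events": scan.events, "truth": truth,
                })
                manifest_rows.append(truth)
    return {
        "scenarios": scenarios,
        "manifest": pd.DataFrame(manifest_rows),
        "master_seed": master_seed,
    }
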