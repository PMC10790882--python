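"""Deceleration-phase segmentation and scenario measures."""

import numpy as np
import pandas as pd
import pytest

from hemisim.config import MetricsConfig
from hemisim.events import Fixation, Saccade
from hemisim.metrics import (aggregate, directional_saccades,
                             first_peripheral_scan, gaze_summary,
                             hemispace_fixations, lane_metrics,
                             missing_large_scans, percentage,
                             segment_deceleration)
from conftest import make_stream


def drive_trace(brake_dist=None, release_dist=None, start=150.0,
                speed_ms=13.89, fs=240.0):
    """Approach at constant speed; brake flag set from brake_dist (released
    again at release_dist if given)."""
    n = int(start / speed_ms * fs) + 2
    t = np.arange(n) / fs
    dist = np.maximum(start - speed_ms * t, 0.0)
    dist[-1] = 0.0
    brake = np.zeros(n, bool)
    if brake_dist is not None:
        brake = dist <= brake_dist
        if release_dist is not None:
            brake = (dist <= brake_dist) & (dist > release_dist)
    return pd.DataFrame({"time": t, "dist": dist,
                         "lane_offset": np.zeros(n), "brake": brake})


class TestSegmentation:
    def test_brake_within_search_distance_starts_window(self):
        win = segment_deceleration(drive_trace(brake_dist=80.0))
        assert win.trigger == "brake"
        d = drive_trace(brake_dist=80.0)
        start_dist = d.loc[d["time"] == win.t_start, "dist"].iloc[0]
        assert start_dist == pytest.approx(80.0, abs=0.1)

    def test_no_braking_falls_back_to_fixed_distance(self):
        win = segment_deceleration(drive_trace(brake_dist=None))
        assert win.trigger == "fallback"
        d = drive_trace()
        start_dist = d.loc[d["time"] == win.t_start, "dist"].iloc[0]
        assert start_dist == pytest.approx(41.76, abs=0.1)

    def test_brake_released_before_search_zone_falls_back(self):
        # brake pressed at 120 m but released at 105 m: nothing within 100 m
        win = segment_deceleration(
            drive_trace(brake_dist=120.0, release_dist=105.0))
        assert win.trigger == "fallback"

    def test_window_ends_at_zebra_crossing(self):
        d = drive_trace(brake_dist=60.0)
        win = segment_deceleration(d)
        assert win.t_end == d["time"].iloc[-1]

    def test_never_reaching_intersection_is_an_error(self):
        d = drive_trace(brake_dist=50.0)
        d = d[d["dist"] > 50.0]
        with pytest.raises(ValueError, match="never reaches"):
            segment_deceleration(d)


class TestLaneMetrics:
    def test_constant_offset(self):
        d = pd.DataFrame({"lane_offset": np.full(100, -17.0)})
        mean, var, crossings = lane_metrics(d)
        assert (mean, var, crossings) == (-17.0, 0.0, 0)

    def test_sinusoid_crosses_once_per_side_per_period(self):
        t = np.arange(0, 3.0, 1 / 240)
        d = pd.DataFrame({"lane_offset": 100.0 * np.sin(2 * np.pi * t / 1.0)})
        _, _, crossings = lane_metrics(d, MetricsConfig(lane_boundary_cm=85.0))
        assert crossings == 6  # 3 periods x 2 sides

    def test_translation_shifts_mean_not_variance(self, rng):
        x = rng.normal(0, 10, 500)
        d1 = pd.DataFrame({"lane_offset": x})
        d2 = pd.DataFrame({"lane_offset": x + 30.0})
        m1, v1, _ = lane_metrics(d1)
        m2, v2, _ = lane_metrics(d2)
        assert m2 - m1 == pytest.approx(30.0)
        assert v1 == pytest.approx(v2)

    def test_variance_unit_conversion(self, rng):
        x = rng.normal(0, 10, 500)
        d = pd.DataFrame({"lane_offset": x})
        _, v_cm2, _ = lane_metrics(d, MetricsConfig(lane_variance_units="cm2"))
        _, v_m2, _ = lane_metrics(d, MetricsConfig(lane_variance_units="m2"))
        assert v_m2 == pytest.approx(v_cm2 / 1e4)


class TestScans:
    def _trace(self):
        az = np.zeros(240)
        az[60:70] = -35.0
        az[120:130] = 50.0
        return make_stream(az)

    def test_first_scan_at_30_deg_threshold(self):
        assert first_peripheral_scan(self._trace(), 30.0) == "left"

    def test_first_scan_at_45_deg_threshold(self):
        assert first_peripheral_scan(self._trace(), 45.0) == "right"

    def test_no_scan_below_threshold(self):
        assert first_peripheral_scan(make_stream(np.full(100, 25.0)), 30.0) == "none"

    @pytest.mark.parametrize("lo, hi, expected", [
        (-55.0, 50.0, (False, False)),
        (-50.0, 30.0, (False, True)),
        (-30.0, 46.0, (True, False)),
    ])
    def test_missing_large_scans(self, lo, hi, expected):
        az = np.concatenate([np.full(50, lo), np.full(50, hi)])
        assert missing_large_scans(make_stream(az), 45.0) == expected


class TestGazeSummary:
    def test_constant_gaze(self):
        var, mean, mn, mx = gaze_summary(make_stream(np.full(50, 5.0)))
        assert (var, mean, mn, mx) == (0.0, 5.0, 5.0, 5.0)

    def test_three_point_sample_statistics(self):
        var, mean, mn, mx = gaze_summary(make_stream([-10.0, 0.0, 10.0]))
        assert mean == 0.0 and mn == -10.0 and mx == 10.0
        assert var == pytest.approx(100.0)  # sample variance, n-1

    def test_negation_symmetry(self, rng):
        az = rng.normal(3, 12, 200)
        v1, m1, lo1, hi1 = gaze_summary(make_stream(az))
        v2, m2, lo2, hi2 = gaze_summary(make_stream(-az))
        assert v1 == pytest.approx(v2)
        assert m2 == pytest.approx(-m1)
        assert (lo2, hi2) == (pytest.approx(-hi1), pytest.approx(-lo1))

    def test_too_few_samples_gives_missing(self):
        out = gaze_summary(make_stream([1.0]))
        assert all(np.isnan(v) for v in out)


def _fix(az, dur=0.3):
    return Fixation(0.0, dur, dur, az, "left" if az < -5 else
                    ("right" if az > 5 else "central"))


def _sacc(start, end):
    return Saccade(0.0, 0.1, abs(end - start),
                   "right" if end >= start else "left", end, 200.0)


class TestHemispaceAndDirectional:
    def test_hemifield_counts_exclude_central_zone(self):
        nl, nr, dl, dr = hemispace_fixations(
            [_fix(-20), _fix(-8), _fix(3), _fix(12)])
        assert (nl, nr) == (2, 1)

    def test_all_central_counts_nothing(self):
        nl, nr, dl, dr = hemispace_fixations([_fix(0), _fix(4), _fix(-5)])
        assert (nl, nr) == (0, 0)
        assert np.isnan(dl) and np.isnan(dr)

    def test_durations_averaged_per_side(self):
        nl, nr, dl, dr = hemispace_fixations(
            [_fix(-20, 0.2), _fix(-30, 0.4), _fix(10, 0.5)])
        assert dl == pytest.approx(0.3) and dr == pytest.approx(0.5)

    def test_directional_saccade_means(self):
        al, ar = directional_saccades([_sacc(0, 20)])
        assert np.isnan(al) and ar == pytest.approx(20.0)

    def test_endpoint_rule_excludes_central_landings(self):
        # leftward saccade ending at +2 deg: endpoint not in the left
        # periphery, so it counts nowhere
        al, ar = directional_saccades([_sacc(10, 2)])
        assert np.isnan(al) and np.isnan(ar)

    def test_mixed_batch_matches_filter_then_average(self, rng):
        sacc = [_sacc(float(rng.uniform(-40, 40)), float(rng.uniform(-60, 60)))
                for _ in range(200)]
        al, ar = directional_saccades(sacc)
        left = [s.amplitude for s in sacc
                if s.direction == "left" and s.endpoint_az < -5]
        right = [s.amplitude for s in sacc
                 if s.direction == "right" and s.endpoint_az > 5]
        assert al == pytest.approx(np.mean(left))
        assert ar == pytest.approx(np.mean(right))


class TestPercentage:
    @pytest.mark.parametrize("k, total, expected", [
        (25, 84, 29.76),
        (19, 84, 22.62),
        (26, 132, 19.70),
        (0, 42, 0.00),
    ])
    def test_reference_counts(self, k, total, expected):
        assert percentage(k, total) == expected

    def test_half_up_rounding(self):
        assert percentage(1, 8000) == 0.01  # 0.0125 -> 0.01
        assert percentage(1, 800) == 0.13   # 0.125 -> 0.13 (half-up)

    def test_scale_free(self, rng):
        for _ in range(50):
            total = int(rng.integers(1, 500))
            k = int(rng.integers(0, total + 1))
            assert percentage(k, total) == percentage(2 * k, 2 * total)

    def test_zero_total_is_undefined(self):
        assert np.isnan(percentage(0, 0))


class TestAggregate:
    def _records(self):
        rows = []
        for s in range(6):
            for cond in ("NV", "LHH", "RHH"):
                for inter in ("SCI", "LTI", "RTI"):
                    rows.append({
                        "subject": f"S{s}", "condition": cond,
                        "intersection": inter, "phase_duration": 8.0,
                        "lane_mean": -15.0, "lane_variance": 1.0,
                        "lane_crossings": int(cond == "RHH" and inter == "SCI"
                                              and s < 2),
                        "first_scan_30": "left" if s % 2 else "right",
                        "first_scan_45": "none",
                        "missing_large_scan_left": cond == "LHH" and s < 3,
                        "missing_large_scan_right": False,
                        "gaze_var": 100.0, "gaze_mean": 0.0,
                        "gaze_min": -50.0, "gaze_max": 50.0,
                        "fix_n_left": 2, "fix_n_right": 3,
                        "fix_dur_left": 0.3, "fix_dur_right": 0.3,
                        "sacc_amp_left": 20.0, "sacc_amp_right": 25.0,
                        "n_fixations": 10, "n_saccades": 9,
                    })
        return pd.DataFrame(rows)

    def test_planted_counts_recovered_exactly(self):
        out = aggregate(self._records())
        missing = out["missing_scans"]
        row = missing[(missing["condition"] == "LHH")
                      & (missing["side"] == "left")].iloc[0]
        assert row["k"] == 9  # 3 subjects x 3 intersections
        assert row["pct"] == percentage(9, 18)
        pooled = missing[(missing["condition"] == "pooled")
                         & (missing["side"] == "left")].iloc[0]
        assert pooled["k"] == 9 and pooled["K"] == 54
        assert out["lane_crossings"]["scenarios_with_crossing"] == 2

    def test_summary_has_condition_by_intersection_rows(self):
        out = aggregate(self._records())
        assert out["summary"].shape[0] == 9
        assert out["summary"].loc[("NV", "SCI"), ("phase_duration", "mean")] \
            == pytest.approx(8.0)
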