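"""Mask-engine geometry: angle conversions, panel mapping, smoothing, fades."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemisim.config import BufferPolicy, MaskSpec, RigGeometry
from hemisim.masking import (AnchorSmoother, azel_to_panel_pixel,
                             azel_to_vector, occluded_fraction, opacity_at,
                             panel_pixel_to_azel, replay_mask, smooth_anchor,
                             vector_to_azel)

RIG = RigGeometry()


class TestVectorToAzel:
    @pytest.mark.parametrize("vec, expected", [
        ((0.0, 0.0, 1.0), (0.0, 0.0)),
        ((np.sin(np.radians(30)), 0.0, np.cos(np.radians(30))), (30.0, 0.0)),
        # frozen values from an independent trigonometric evaluation
        ((0.25, 0.25, 0.9354), (14.9634, 14.4777)),
    ])
    def test_known_directions(self, vec, expected):
        az, el, valid = vector_to_azel(*vec)
        assert valid
        assert az == pytest.approx(expected[0], abs=0.01)
        assert el == pytest.approx(expected[1], abs=0.01)

    def test_zero_vector_flagged_invalid_not_raised(self):
        az, el, valid = vector_to_azel(0.0, 0.0, 0.0)
        assert not valid and np.isnan(az) and np.isnan(el)

    @given(az=st.floats(-179.0, 179.0), el=st.floats(-89.0, 89.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip(self, az, el):
        x, y, z = azel_to_vector(az, el)
        az2, el2, valid = vector_to_azel(x, y, z)
        assert valid
        assert az2 == pytest.approx(az, abs=1e-6)
        assert el2 == pytest.approx(el, abs=1e-6)


class TestPanelMapping:
    @pytest.mark.parametrize("az, el, panel, px_x, px_y", [
        (0.0, 0.0, 1, 1700.0, 1360.0),      # rig center
        (30.0, 0.0, 2, 0.0, 1360.0),        # sector boundary, right owns +30
        (15.0, 0.0, 1, 2488.97, 1360.0),    # 1700*(1 + tan15/tan30)
        (-90.0, 0.0, 0, 0.0, 1360.0),
        (90.0, 0.0, 2, 3400.0, 1360.0),
    ])
    def test_known_anchors(self, az, el, panel, px_x, px_y):
        anchor = azel_to_panel_pixel(az, el, RIG)
        assert anchor.panel_index == panel
        assert anchor.px_x == pytest.approx(px_x, abs=0.5)
        assert anchor.px_y == pytest.approx(px_y, abs=0.5)

    def test_out_of_field_clamped_and_flagged(self):
        anchor = azel_to_panel_pixel(120.0, 0.0, RIG)
        assert anchor.clamped and anchor.panel_index == 2
        assert anchor.px_x == pytest.approx(3400.0, abs=0.5)

    def test_sector_tiling_and_pixel_round_trip(self, rng):
        az = rng.uniform(-90.0, 90.0 - 1e-9, 10_000)
        el = rng.uniform(-RIG.vertical_half_angle_deg + 0.01,
                         RIG.vertical_half_angle_deg - 0.01, az.size)
        half = RIG.panel_half_angle_deg
        for a, e in zip(az, el):
            anchor = azel_to_panel_pixel(a, e, RIG)
            owners = sum(
                lo <= a < hi
                for lo, hi in ((-90, -half), (-half, half), (half, 90))
            )
            assert owners == 1
            assert 0 <= anchor.px_x <= RIG.panel_px_w
            a2, e2 = panel_pixel_to_azel(anchor.panel_index, anchor.px_x,
                                         anchor.px_y, RIG)
            back = azel_to_panel_pixel(a2, e2, RIG)
            assert abs(back.px_x - anchor.px_x) < 0.5
            assert abs(back.px_y - anchor.px_y) < 0.5


class TestAnchorSmoother:
    def test_steady_state_reproduces_constant(self):
        assert smooth_anchor([5.0] * 10) == pytest.approx(5.0)

    def test_moving_average_of_window(self):
        # window 3, no bypass: mean of 0, 3, 6
        policy = BufferPolicy(window_len=3, bypass_threshold_deg=10.0)
        assert smooth_anchor([0.0, 3.0, 6.0], policy=policy) == pytest.approx(3.0)

    def test_large_step_bypasses_buffer_in_one_sample(self):
        policy = BufferPolicy(window_len=3, bypass_threshold_deg=10.0)
        sm = AnchorSmoother(policy)
        for _ in range(5):
            sm.update(0.0)
        out, held = sm.update(40.0)
        assert out == pytest.approx(40.0) and not held

    def test_small_step_tracked_within_window(self):
        policy = BufferPolicy(window_len=3, bypass_threshold_deg=10.0)
        sm = AnchorSmoother(policy)
        for _ in range(5):
            sm.update(0.0)
        outs = [sm.update(8.0)[0] for _ in range(policy.window_len)]
        assert outs[-1] == pytest.approx(8.0)

    def test_invalid_samples_hold_last_output(self):
        sm = AnchorSmoother()
        sm.update(12.0)
        out, held = sm.update(np.nan, valid=False)
        assert held and out == pytest.approx(12.0)

    def test_all_invalid_history_holds_center_with_warning(self):
        with pytest.warns(UserWarning, match="invalid"):
            out = smooth_anchor([np.nan, np.nan], valid=[False, False])
        assert out == 0.0


class TestOpacity:
    def test_hard_edge(self):
        spec = MaskSpec(side="left", fade_width_deg=0.0)
        assert opacity_at(-10.0, 0.0, spec) == 1.0
        assert opacity_at(10.0, 0.0, spec) == 0.0

    def test_ramp_midpoint(self):
        spec = MaskSpec(side="left", fade_width_deg=4.0)
        assert opacity_at(0.0, 0.0, spec) == pytest.approx(0.5)

    def test_right_side_linear_interpolation(self):
        spec = MaskSpec(side="right", fade_width_deg=10.0)
        assert opacity_at(22.5, 20.0, spec) == pytest.approx(0.75)

    def test_monotone_in_azimuth(self, rng):
        for side, sign in (("left", -1), ("right", 1)):
            spec = MaskSpec(side=side, fade_width_deg=float(rng.uniform(0, 20)))
            az = np.linspace(-90, 90, 721)
            alpha = opacity_at(az, float(rng.uniform(-40, 40)), spec)
            assert np.all(sign * np.diff(alpha) >= -1e-12)


class TestOccludedFraction:
    @pytest.mark.parametrize("side, anchor, fade, expected", [
        ("left", 0.0, 0.0, 0.5),
        ("left", 45.0, 8.0, 0.75),
        ("right", -30.0, 10.0, 2.0 / 3.0),
    ])
    def test_known_fractions(self, side, anchor, fade, expected):
        spec = MaskSpec(side=side, fade_width_deg=fade)
        assert occluded_fraction(anchor, spec) == pytest.approx(expected, abs=1e-9)

    def test_matches_numeric_integration(self, rng):
        az = np.arange(-90.0, 90.0, 0.01)
        for _ in range(20):
            spec = MaskSpec(side=rng.choice(["left", "right"]),
                            fade_width_deg=float(rng.uniform(0, 30)))
            anchor = float(rng.uniform(-80, 80))
            numeric = float(np.mean(opacity_at(az, anchor, spec)))
            assert occluded_fraction(anchor, spec) == pytest.approx(
                numeric, abs=1e-3)

    def test_fade_inside_field_equals_hard_edge_value(self, rng):
        for _ in range(20):
            anchor = float(rng.uniform(-60, 60))
            fade = float(rng.uniform(0, 2 * (90 - abs(anchor))))
            hard = occluded_fraction(anchor, MaskSpec("left", 0.0))
            soft = occluded_fraction(anchor, MaskSpec("left", fade))
            assert soft == pytest.approx(hard, abs=1e-9)


class TestReplay:
    def _log(self, az, valid=None, fs=60.0):
        az = np.asarray(az, float)
        return pd.DataFrame({
            "time": np.arange(az.size) / fs,
            "az": az,
            "el": np.zeros(az.size),
            "valid": np.ones(az.size, bool) if valid is None else valid,
        })

    def test_constant_gaze_constant_anchor(self):
        out = replay_mask(self._log(np.full(60, 10.0)))
        assert len(out) == 60
        assert not out["held"].any()
        assert out["anchor_az"].iloc[-1] == pytest.approx(10.0)
        assert (out["lag_samples"] == 0).all()

    def test_dropout_holds_anchor_and_counts_lag(self):
        az = np.full(30, 5.0)
        valid = np.ones(30, bool)
        az[10:15] = np.nan
        valid[10:15] = False
        out = replay_mask(self._log(az, valid))
        assert out["held"].iloc[10:15].all()
        assert np.allclose(out["anchor_az"].iloc[10:15], 5.0)
        assert list(out["lag_samples"].iloc[10:16]) == [1, 2, 3, 4, 5, 0]

    def test_large_step_tracked_in_one_sample(self):
        az = np.concatenate([np.zeros(30), np.full(30, 30.0)])
        out = replay_mask(self._log(az))
        assert out["anchor_az"].iloc[30] == pytest.approx(30.0)

    def test_non_monotone_time_names_offending_index(self):
        log = self._log(np.zeros(10))
        log.loc[4, "time"] = log.loc[2, "time"]
        with pytest.raises(ValueError, match="index 4"):
            replay_mask(log)

    def test_replay_is_deterministic(self):
        log = self._log(np.cumsum(np.sin(np.arange(100))))
        a = replay_mask(log)
        b = replay_mask(log.copy())
        pd.testing.assert_frame_equal(a, b)
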