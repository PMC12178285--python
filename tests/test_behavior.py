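"""Zone occupancy, discrimination index and USV modulation index."""

import numpy as np
import pandas as pd
import pytest

from neocoupling.behavior import (
    ArenaGeometry,
    OccupancyResult,
    discrimination_index,
    usv_modulation_index,
    zone_occupancy,
)
from neocoupling.errors import ParameterError, QualityError, UndefinedValueError
from neocoupling.signal_io import CallTable, TrackTable
from neocoupling.synthetic_data import SyntheticConfig, generate_behavior_session


def track_at(x_values, fps=30.0, likelihood=1.0):
    n = len(x_values)
    return TrackTable(
        df=pd.DataFrame(
            {
                "frame": np.arange(n),
                "x_cm": np.asarray(x_values, dtype=float),
                "y_cm": np.zeros(n),
                "likelihood": np.full(n, likelihood),
            }
        ),
        fps=fps,
    )


def call_table(onsets):
    onsets = np.asarray(onsets, dtype=float)
    return CallTable(
        df=pd.DataFrame(
            {"t_on": onsets, "t_off": onsets + 0.05, "peak_freq_khz": np.full(len(onsets), 60.0)}
        )
    )


class TestZoneOccupancy:
    def test_single_zone_stay(self):
        occ = zone_occupancy(track_at([2.0] * (30 * 180)), test_side="left")
        assert occ.t_test == pytest.approx(180.0)
        assert occ.t_control == 0.0 and occ.t_neutral == 0.0

    def test_arena_center_is_neutral(self):
        occ = zone_occupancy(track_at([8.75] * 30))
        assert occ.t_neutral == pytest.approx(1.0)
        assert occ.t_test == 0.0 and occ.t_control == 0.0

    def test_low_likelihood_frames_excluded_and_counted(self):
        t = track_at([2.0] * 60)
        t.df.loc[:9, "likelihood"] = 0.2
        occ = zone_occupancy(t, test_side="left")
        assert occ.n_excluded_frames == 10
        assert occ.t_test == pytest.approx(50 / 30.0)

    def test_all_frames_excluded_raises(self):
        with pytest.raises(QualityError):
            zone_occupancy(track_at([2.0] * 30, likelihood=0.1))

    def test_zone_times_plus_excluded_reconstruct_session(self):
        cfg = SyntheticConfig(seed=5)
        track, _, gt = generate_behavior_session(cfg)
        occ = zone_occupancy(track, test_side=cfg.test_side, likelihood_min=cfg.likelihood_min)
        total_frames = (
            (occ.t_test + occ.t_control + occ.t_neutral) * cfg.fps + occ.n_excluded_frames
        )
        assert total_frames == pytest.approx(len(track.df))

    def test_occupancy_matches_generator_bookkeeping_exactly(self):
        cfg = SyntheticConfig(seed=6)
        track, _, gt = generate_behavior_session(cfg)
        occ = zone_occupancy(track, test_side=cfg.test_side, likelihood_min=cfg.likelihood_min)
        assert occ.t_test == pytest.approx(gt.dwell_s["test"], abs=1e-12)
        assert occ.t_control == pytest.approx(gt.dwell_s["control"], abs=1e-12)
        assert occ.t_neutral == pytest.approx(gt.dwell_s["neutral"], abs=1e-12)
        assert occ.n_excluded_frames == gt.n_excluded_frames

    def test_time_shift_invariance(self):
        t1 = track_at([2.0, 9.0, 15.0] * 100)
        t2 = track_at([2.0, 9.0, 15.0] * 100)
        t2.df["frame"] += 500
        a = zone_occupancy(t1)
        b = zone_occupancy(t2)
        assert (a.t_test, a.t_control, a.t_neutral) == (b.t_test, b.t_control, b.t_neutral)


class TestDiscriminationIndex:
    @pytest.mark.parametrize(
        "t_test,t_control,expected",
        [(60.0, 60.0, 0.0), (60.0, 0.0, 1.0), (0.0, 60.0, -1.0), (90.0, 30.0, 0.5)],
    )
    def test_reference_values(self, t_test, t_control, expected):
        occ = OccupancyResult(t_test, t_control, 0.0, 0)
        assert discrimination_index(occ).di == pytest.approx(expected)

    def test_side_swap_negates(self):
        track = track_at([2.0] * 90 + [15.0] * 30)
        left = discrimination_index(zone_occupancy(track, test_side="left")).di
        right = discrimination_index(zone_occupancy(track, test_side="right")).di
        assert left == pytest.approx(-right)
        assert left == pytest.approx(0.5)

    def test_undefined_without_zone_time(self):
        with pytest.raises(UndefinedValueError):
            discrimination_index(OccupancyResult(0.0, 0.0, 120.0, 0))


class TestUsvModulation:
    def test_equal_rates_give_zero(self):
        calls = call_table(np.concatenate([np.arange(0, 60, 6), np.arange(60, 120, 6)]))
        mi = usv_modulation_index(calls, odor_window=(60, 120), baseline_window=(0, 60))
        assert mi.mi == pytest.approx(0.0)

    def test_full_suppression_is_minus_one(self):
        calls = call_table(np.arange(0, 60, 6))
        mi = usv_modulation_index(calls, odor_window=(60, 120), baseline_window=(0, 60))
        assert mi.mi == -1.0

    def test_poisson_ratio_three_to_one(self, rng):
        t_base = np.sort(rng.uniform(0, 3000, rng.poisson(1.0 * 3000)))
        t_odor = np.sort(rng.uniform(3000, 6000, rng.poisson(3.0 * 3000)))
        calls = call_table(np.concatenate([t_base, t_odor]))
        mi = usv_modulation_index(calls, odor_window=(3000, 6000), baseline_window=(0, 3000))
        # delta-method SE of the 3:1 difference-over-sum at these window sizes
        se = 0.012
        assert mi.mi == pytest.approx(0.5, abs=3 * se)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ParameterError):
            usv_modulation_index(call_table([1.0]), (0, 60), (30, 90))

    def test_no_calls_undefined(self):
        calls = call_table(np.array([200.0]))
        with pytest.raises(UndefinedValueError):
            usv_modulation_index(calls, (60, 120), (0, 60))

    def test_generator_suppression_boundary(self):
        cfg = SyntheticConfig(seed=9, call_suppression=0.0)
        _, calls, gt = generate_behavior_session(cfg)
        base_s, odor_s, post_s, break_s = cfg.usv_trial_s
        trial = 2  # the concentration with suppression applied
        t0 = trial * (base_s + odor_s + post_s + break_s)
        mi = usv_modulation_index(
            calls, odor_window=(t0 + base_s, t0 + base_s + odor_s), baseline_window=(t0, t0 + base_s)
        )
        assert mi.mi == -1.0


class TestArena:
    def test_geometry_must_close(self):
        with pytest.raises(ParameterError):
            ArenaGeometry(length_cm=17.5, zone_cm=6.0, neutral_cm=4.5)
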