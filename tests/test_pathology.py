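"""Relapse detection, calibration mapping and the EBV trigger contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rrmsim.params import EngineParams
from rrmsim.pathology import (CalibrationError, PatientProfile, RelapseEvent,
                              cumulative_oligo_loss, detect_relapses,
                              load_calibration_table,
                              map_characteristics_to_params, trigger_ebv_event)
from rrmsim.engine import make_initial_state


BASE = 200
THETA = 0.05
W = 14
GAP = 30


def detect(traj):
    return detect_relapses(traj, baseline=BASE, theta=THETA, window=W, min_gap=GAP)


class TestRelapseDetector:
    def test_constant_trajectory_has_no_episodes(self):
        assert detect([BASE] * 500) == []

    def test_empty_trajectory(self):
        assert detect([]) == []

    def test_single_sharp_drop_is_one_event_with_drop_magnitude(self):
        drop = int(2 * THETA * BASE)   # 20 cells, twice the threshold
        traj = [BASE] * 100 + [BASE - drop] * 200
        events = detect(traj)
        assert len(events) == 1
        assert events[0].start_time == 100
        assert events[0].magnitude == drop

    def test_sawtooth_gives_three_events(self):
        traj = []
        level = BASE
        for _ in range(3):
            traj += [level] * 80
            level -= 15                 # drop of 15 >= theta * baseline
            traj += [level] * 80
            level = BASE                # full remyelination between episodes
        events = detect(traj)
        assert len(events) == 3
        assert all(ev.magnitude >= THETA * BASE for ev in events)
        starts = [ev.start_time for ev in events]
        assert starts == sorted(starts)

    def test_subthreshold_loss_is_ignored(self):
        traj = [BASE] * 50 + [BASE - 5] * 200   # 5 < 10 = theta * baseline
        assert detect(traj) == []

    def test_slow_drift_below_threshold_rate_is_ignored(self):
        # loses 1 cell every 60 steps: never 10 within any 14-step window
        traj = [BASE - (t // 60) for t in range(3000)]
        assert detect(traj) == []

    def test_detector_is_pure_and_tail_invariant(self):
        traj = [BASE] * 40 + [BASE - 25] * 100
        ev1 = detect(traj)
        ev2 = detect(traj)
        ev3 = detect(traj + [traj[-1]] * 500)
        assert ev1 == ev2 == ev3

    def test_close_episodes_merge(self):
        # second drop re-opens within min_gap of the first episode's end
        traj = [BASE] * 50 + [BASE - 12] * 10 + [BASE - 24] * 100
        events = detect(traj)
        assert len(events) == 1
        assert events[0].magnitude == 24

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            detect_relapses([BASE] * 10, BASE, theta=1.5, window=W, min_gap=GAP)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_trajectories_satisfy_event_invariants(self, seed):
        rng = np.random.default_rng(seed)
        traj = BASE - np.cumsum(rng.choice([0, 0, 0, 1, -1], size=400)).clip(0, 60)
        events = detect(traj)
        for prev, nxt in zip(events, events[1:]):
            assert nxt.start_time - prev.end_time >= GAP
        for ev in events:
            assert ev.end_time >= ev.start_time
            assert ev.magnitude >= THETA * BASE


class TestCumulativeLoss:
    def test_summation(self):
        evs = [RelapseEvent(0, 1, 10), RelapseEvent(100, 110, 25),
               RelapseEvent(300, 301, 5)]
        assert cumulative_oligo_loss(evs) == 40
        assert cumulative_oligo_loss([]) == 0
        assert cumulative_oligo_loss([RelapseEvent(2, 3, 40)]) == 40


class TestCalibrationMapping:
    def test_table_covers_all_twelve_combinations(self):
        table = load_calibration_table()
        assert len(table) == 12

    def test_same_profile_same_overrides(self):
        p = PatientProfile("HIGH", "PRESENT", "30-39", seed=1)
        assert map_characteristics_to_params(p) == map_characteristics_to_params(p)

    def test_high_lesion_load_is_monotone_in_autoreactivity(self):
        for ocb in ("PRESENT", "ABSENT"):
            for age in ("18-29", "30-39", "40-49"):
                hi = map_characteristics_to_params(
                    PatientProfile("HIGH", ocb, age, seed=0))
                lo = map_characteristics_to_params(
                    PatientProfile("LOW_MEDIUM", ocb, age, seed=0))
                assert hi["p_auto"] >= lo["p_auto"]
                assert hi["p_kill_ctl"] >= lo["p_kill_ctl"]

    def test_ocb_presence_extends_plasma_persistence(self):
        pres = map_characteristics_to_params(
            PatientProfile("HIGH", "PRESENT", "30-39", seed=0))
        absent = map_characteristics_to_params(
            PatientProfile("HIGH", "ABSENT", "30-39", seed=0))
        assert pres["death_plasma"] <= absent["death_plasma"]

    def test_missing_combination_is_a_configuration_error(self):
        p = PatientProfile("HIGH", "PRESENT", "30-39", seed=0)
        with pytest.raises(CalibrationError):
            map_characteristics_to_params(p, calibration={})

    def test_invalid_categories_rejected(self):
        with pytest.raises(ValueError):
            PatientProfile("VERY_HIGH", "PRESENT", "30-39")
        with pytest.raises(ValueError):
            PatientProfile("HIGH", "MAYBE", "30-39")
        with pytest.raises(ValueError):
            PatientProfile("HIGH", "PRESENT", "50-59")


class TestEbvTrigger:
    def test_trigger_fires_once_and_only_once(self, default_params, rng):
        state = make_initial_state(default_params, rng)
        trigger_ebv_event(state, 10)
        assert state.ebv_fired and state.viral_load > 0
        with pytest.raises(RuntimeError):
            trigger_ebv_event(state, 20)

    def test_mimicry_zero_flips_targets_the_self_epitope(self, default_params, rng):
        state = make_initial_state(default_params, rng)
        trigger_ebv_event(state, 0)
        if default_params.mimicry_flips == 0:
            assert state.viral_antigen == default_params.self_antigen

    def test_negative_flips_draw_unrelated_epitope(self, rng):
        params = EngineParams.with_overrides({"mimicry_flips": -1})
        state = make_initial_state(params, rng)
        trigger_ebv_event(state, 0)
        assert state.viral_antigen is not None
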