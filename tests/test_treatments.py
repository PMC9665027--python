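"""Dosing schedules, effect envelopes and mechanism-of-action contracts."""

import numpy as np
import pytest

from rrmsim.agents import CellState, CellType, Compartment
from rrmsim.engine import make_initial_state, run_steps, step
from rrmsim.params import EngineParams
from rrmsim.treatments import (DRUG_PD, DrugEffectState, NATALIZUMAB_AFFIRM,
                               TreatmentPlan, apply_drug, apply_ifnb1a,
                               apply_natalizumab, apply_ocrelizumab,
                               apply_teriflunomide, effect_at,
                               make_treatment_hook, schedule_doses,
                               update_effect)


class TestSchedule:
    def test_affirm_regimen_has_26_administrations(self):
        """300 mg every 4 weeks for 104 weeks: 104*7/28 = 26 doses."""
        doses = schedule_doses(NATALIZUMAB_AFFIRM, trial_weeks=104, steps_per_day=1)
        assert len(doses) == 26
        assert doses[0] == 0
        assert doses[1] - doses[0] == 28

    def test_no_drug_means_no_doses(self):
        assert schedule_doses(TreatmentPlan(), 104) == []

    def test_dosing_stops_at_treatment_window_end(self):
        plan = TreatmentPlan(drug="NATALIZUMAB", dose_mg=300, interval_days=28,
                             start_week=0, end_week=8)
        doses = schedule_doses(plan, trial_weeks=104, steps_per_day=1)
        # window [0, 8) weeks: administrations at days 0 and 28 only
        assert doses == [0, 28]

    def test_trial_length_clips_the_window(self):
        doses = schedule_doses(NATALIZUMAB_AFFIRM, trial_weeks=8, steps_per_day=1)
        assert doses == [0, 28]

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            TreatmentPlan(drug="ASPIRIN")
        with pytest.raises(ValueError):
            TreatmentPlan(drug="NATALIZUMAB", interval_days=0, end_week=1)
        with pytest.raises(ValueError):
            TreatmentPlan(drug="NATALIZUMAB", interval_days=28,
                          start_week=10, end_week=5)


class TestEffectEnvelope:
    def test_zero_before_first_dose_and_peak_at_dose(self):
        admins = [100, 200]
        assert effect_at(50, admins, half_life_days=14, steps_per_day=1) == 0.0
        assert effect_at(100, admins, half_life_days=14, steps_per_day=1) == 1.0
        assert effect_at(200, admins, half_life_days=14, steps_per_day=1) == 1.0

    def test_exponential_decay_half_life(self):
        """14 days after a dose with a 14-day half-life: effect 0.5."""
        e = effect_at(14, [0], half_life_days=14.0, steps_per_day=1)
        assert e == pytest.approx(0.5, abs=1e-12)

    def test_update_effect_tracks_last_administration(self):
        st = DrugEffectState(drug="NATALIZUMAB")
        update_effect(st, t=30, administrations=[0, 28], steps_per_day=1)
        assert st.last_admin == 28
        hl = DRUG_PD["NATALIZUMAB"]["half_life_days"]
        assert st.effect == pytest.approx(0.5 ** (2 / hl), abs=1e-12)

    def test_dose_saturation_reaches_near_full_effect_at_label_dose(self):
        assert NATALIZUMAB_AFFIRM.peak_effect > 0.95


class TestMechanisms:
    def test_zero_effect_is_mechanically_neutral(self, default_params, rng):
        state = make_initial_state(default_params, rng)
        before = dict(state.modifiers)
        for fn in (apply_natalizumab, apply_ocrelizumab, apply_ifnb1a,
                   apply_teriflunomide):
            fn(state, 0.0)
        assert state.modifiers == before

    def test_natalizumab_scales_migration_arithmetic(self, default_params, rng):
        """effect 0.5 with e_max 1: a baseline migration probability of
        0.2 becomes 0.1."""
        state = make_initial_state(default_params, rng)
        apply_natalizumab(state, 0.5)
        assert 0.2 * state.modifiers["mig_factor"] == pytest.approx(0.1)

    def test_full_natalizumab_blocks_all_white_matter_entry(self, rng):
        params = EngineParams.with_overrides({"p_mig_eff": 1.0})
        state = make_initial_state(params, rng)
        pool = state.pool
        # force a cohort of activated effectors in the periphery
        th = np.flatnonzero(pool.mask(CellType.TH))[:40]
        pool.state[th] = CellState.ACTIVATED
        apply_natalizumab(state, 1.0)
        step(state)
        assert state.log_immigration.sum() == 0

    def test_natalizumab_leaves_peripheral_counts_untouched_in_one_step(
            self, default_params, rng):
        state = make_initial_state(default_params, rng)
        n_before = {ct: state.pool.count(ct) for ct in CellType}
        apply_natalizumab(state, 1.0)
        n_after = {ct: state.pool.count(ct) for ct in CellType}
        assert n_before == n_after

    def test_ocrelizumab_depletes_b_cells_binomially(self, rng):
        """effect 1, k_ocr 0.5: about half of the B cells die per step."""
        from rrmsim.treatments import K_OCRELIZUMAB
        losses = []
        for seed in range(30):
            params = EngineParams.with_overrides()
            state = make_initial_state(params, np.random.default_rng(seed))
            state.hematopoiesis_enabled = False
            nb0 = state.pool.count(CellType.B)
            apply_ocrelizumab(state, 1.0)
            step(state)
            losses.append(nb0 - state.pool.count(CellType.B))
        nb0 = EngineParams.with_overrides().setpoint_B
        p_die = 1 - (1 - 0.012) * (1 - K_OCRELIZUMAB)  # drug + background
        mean = np.mean(losses)
        se = np.sqrt(nb0 * p_die * (1 - p_die) / len(losses))
        assert abs(mean - nb0 * p_die) < 4 * se

    def test_ifnb1a_and_teriflunomide_set_documented_factors(self, default_params, rng):
        from rrmsim.treatments import G_IFNB1A, K_IFNB1A, K_TERIFLUNOMIDE
        state = make_initial_state(default_params, rng)
        apply_ifnb1a(state, 0.6)
        assert state.modifiers["act_factor"] == pytest.approx(1 - 0.6 * K_IFNB1A)
        assert state.modifiers["dup_factor"] == pytest.approx(1 - 0.6 * K_IFNB1A)
        assert state.modifiers["tgfb_factor"] == pytest.approx(1 + 0.6 * G_IFNB1A)
        apply_teriflunomide(state, 0.5)
        assert state.modifiers["dup_factor_activated"] == pytest.approx(
            1 - 0.5 * K_TERIFLUNOMIDE)

    def test_effect_out_of_range_rejected(self, default_params, rng):
        state = make_initial_state(default_params, rng)
        with pytest.raises(ValueError):
            apply_natalizumab(state, 1.5)

    def test_none_plan_reproduces_naive_run_bit_identically(self, default_params):
        """A NONE treatment hook leaves the trajectory exactly equal to a
        hook-free run at the same seed."""
        from rrmsim.pathology import trigger_ebv_event

        def run(hook):
            state = make_initial_state(default_params, np.random.default_rng(21))
            trigger_ebv_event(state, 0)
            return run_steps(state, 80, hook=hook)

        none_hook = make_treatment_hook(TreatmentPlan(), trial_weeks=12)
        assert none_hook is None
        zero_effect = lambda st, i: apply_drug(st, "NATALIZUMAB", 0.0)
        t_naive = run(None)
        t_zero = run(zero_effect)
        assert np.array_equal(t_naive, t_zero)
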