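"""Trial-engine contracts: sampling, inclusion, randomization, configs."""

import numpy as np
import pytest
from scipy.stats import chisquare

from rrmsim.pathology import RelapseEvent
from rrmsim.treatments import NATALIZUMAB_AFFIRM, TreatmentPlan
from rrmsim.trial import (Arm, ConfigError, InclusionCriteria, PopulationSpec,
                          TrialConfig, apply_inclusion, randomize,
                          sample_population)

AFFIRM_ONSET = {"18-29": 0.494, "30-39": 0.362, "40-49": 0.144}


def _spec(**kw):
    base = dict(lesion_load_dist={"HIGH": 1.0},
                ocb_dist={"PRESENT": 1.0},
                onset_age_dist=AFFIRM_ONSET,
                disease_duration_years=5.0,
                n_candidates=10)
    base.update(kw)
    return PopulationSpec(**base)


class TestSampler:
    def test_onset_distribution_reproduced_at_large_n(self):
        """10000 draws of the 49.4 : 36.2 : 14.4 onset split land within
        1.5 percentage points of the specification."""
        profiles = sample_population(_spec(n_candidates=10000), seed=123)
        frac = {a: np.mean([p.onset_age == a for p in profiles])
                for a in AFFIRM_ONSET}
        for a, target in AFFIRM_ONSET.items():
            assert abs(frac[a] - target) < 0.015

    def test_chi_square_goodness_of_fit_not_rejected(self):
        profiles = sample_population(_spec(n_candidates=10000), seed=9)
        obs = [sum(p.onset_age == a for p in profiles) for a in AFFIRM_ONSET]
        exp = [10000 * v for v in AFFIRM_ONSET.values()]
        _, p = chisquare(obs, exp)
        assert p > 0.01

    def test_point_mass_spec_is_degenerate(self):
        profiles = sample_population(_spec(n_candidates=50), seed=1)
        assert all(p.lesion_load == "HIGH" for p in profiles)
        assert all(p.ocb_status == "PRESENT" for p in profiles)

    def test_same_seed_reproduces_profiles(self):
        a = sample_population(_spec(), seed=5)
        b = sample_population(_spec(), seed=5)
        assert a == b

    def test_batched_sampling_extends_deterministically(self):
        """Patient seeds depend only on (population seed, index), so later
        batches never collide with earlier ones."""
        first = sample_population(_spec(), seed=5, n=10, start_index=0)
        second = sample_population(_spec(), seed=5, n=10, start_index=10)
        seeds = {p.seed for p in first} | {p.seed for p in second}
        assert len(seeds) == 20

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ConfigError):
            _spec(lesion_load_dist={"HIGH": 0.7, "LOW_MEDIUM": 0.5})
        with pytest.raises(ConfigError):
            _spec(onset_age_dist={"18-29": 1.2, "30-39": -0.2})
        with pytest.raises(ConfigError):
            _spec(ocb_dist={"POSITIVE": 1.0})


def _ev(start_day):
    return RelapseEvent(start_day, start_day + 5, 12)


class TestInclusion:
    CRIT = InclusionCriteria(min_relapses_lookback=1, lookback_window_days=365,
                             exclusion_window_days=30, require_symptomatic=True)

    def test_relapse_six_months_ago_included(self):
        assert apply_inclusion([_ev(1825 - 180)], self.CRIT, 1825, 1)

    def test_relapse_in_final_month_excluded(self):
        assert not apply_inclusion([_ev(1825 - 180), _ev(1825 - 14)],
                                   self.CRIT, 1825, 1)

    def test_empty_history_excluded(self):
        assert not apply_inclusion([], self.CRIT, 1825, 1)

    def test_old_relapse_only_excluded(self):
        assert not apply_inclusion([_ev(100)], self.CRIT, 1825, 1)

    def test_agrees_with_brute_force_on_random_histories(self, rng):
        """Window logic matches an independent interval check on 1000
        random histories and screening times."""
        for _ in range(1000):
            n_ev = int(rng.integers(0, 6))
            starts = np.sort(rng.integers(0, 1825, size=n_ev))
            history = [_ev(int(s)) for s in starts]
            t_screen = int(rng.integers(400, 2000))
            crit = InclusionCriteria(
                min_relapses_lookback=int(rng.integers(1, 3)),
                lookback_window_days=float(rng.integers(100, 500)),
                exclusion_window_days=float(rng.integers(0, 60)),
                require_symptomatic=bool(rng.integers(0, 2)))
            got = apply_inclusion(history, crit, t_screen, 1)
            past = [s for s in starts if s <= t_screen]
            in_look = [s for s in past if t_screen - crit.lookback_window_days <= s]
            in_excl = [s for s in past if t_screen - crit.exclusion_window_days <= s]
            want = (len(in_look) >= crit.min_relapses_lookback
                    and not in_excl
                    and (bool(past) or not crit.require_symptomatic))
            assert got == want, (starts, t_screen, crit)

    def test_exclusion_window_cannot_exceed_lookback(self):
        with pytest.raises(ConfigError):
            InclusionCriteria(lookback_window_days=30, exclusion_window_days=60)


def _profiles(n, seed=0):
    return sample_population(_spec(n_candidates=n), seed=seed)


ARMS = [Arm("treated", NATALIZUMAB_AFFIRM, 8), Arm("control", TreatmentPlan(), 4)]


class TestRandomize:
    def test_exact_target_sizes(self):
        out = randomize(_profiles(15), ARMS, [2, 1], seed=3)
        assert len(out["treated"]) == 8 and len(out["control"]) == 4

    def test_one_to_one_split(self):
        arms = [Arm("a", TreatmentPlan(), 5), Arm("b", TreatmentPlan(), 5)]
        out = randomize(_profiles(10), arms, [1, 1], seed=3)
        assert len(out["a"]) == len(out["b"]) == 5

    def test_deterministic_and_order_invariant(self):
        pats = _profiles(15)
        out1 = randomize(pats, ARMS, [2, 1], seed=3)
        out2 = randomize(list(reversed(pats)), ARMS, [2, 1], seed=3)
        assert {p.seed for p in out1["treated"]} == {p.seed for p in out2["treated"]}

    def test_each_patient_in_exactly_one_arm(self):
        out = randomize(_profiles(12), ARMS, [2, 1], seed=1)
        seeds = [p.seed for arm in out.values() for p in arm]
        assert len(seeds) == len(set(seeds)) == 12

    def test_insufficient_patients_error_names_shortfall(self):
        with pytest.raises(ValueError, match="short by 2"):
            randomize(_profiles(10), ARMS, [2, 1], seed=1)


class TestParallelScheduling:
    def test_worker_count_does_not_change_results(self):
        """Per-patient RNG streams make the population run identical for
        any --jobs value."""
        from rrmsim.trial import simulate_population
        spec = _spec(n_candidates=2, disease_duration_years=1.5)
        serial = simulate_population(spec, seed=77, jobs=1)
        parallel = simulate_population(spec, seed=77, jobs=2)
        for a, b in zip(serial.patients, parallel.patients):
            assert a.profile == b.profile
            assert a.runin_relapses == b.runin_relapses
            assert a.immune_means == b.immune_means


class TestTrialConfig:
    def test_milestone_beyond_trial_rejected(self):
        with pytest.raises(ConfigError):
            TrialConfig(population=_spec(), criteria=InclusionCriteria(),
                        arms=ARMS, allocation_ratio=[2, 1],
                        trial_weeks=104, milestones=[120])

    def test_zero_length_trial_rejected(self):
        with pytest.raises(ConfigError, match="empty trial"):
            TrialConfig(population=_spec(), criteria=InclusionCriteria(),
                        arms=ARMS, allocation_ratio=[2, 1], trial_weeks=0)

    def test_ratio_must_match_arms(self):
        with pytest.raises(ConfigError):
            TrialConfig(population=_spec(), criteria=InclusionCriteria(),
                        arms=ARMS, allocation_ratio=[2], trial_weeks=10)
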