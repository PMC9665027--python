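"""Survival estimation and two-sample tests against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from rrmsim.stats import (greenwood_ci, km_estimate, ks_two_sample,
                          wilcoxon_rank_sum)


class TestKaplanMeier:
    def test_hand_worked_four_subject_example(self):
        """times [5,10,10,15], events [T,T,F,T]: S = 3/4, 3/4*2/3, 0."""
        curve = km_estimate([5, 10, 10, 15], [True, True, False, True])
        assert curve.event_times.tolist() == [5, 10, 15]
        np.testing.assert_allclose(curve.estimate, [0.75, 0.5, 0.0], atol=1e-15)
        assert curve.at(0) == 1.0
        assert curve.at(7) == 0.75
        assert curve.at(12) == 0.5
        assert curve.at(99) == 0.0

    def test_no_events_gives_unit_survival(self):
        curve = km_estimate([10, 10, 10], [False, False, False])
        assert len(curve.event_times) == 0
        assert curve.at(5) == 1.0 and curve.at(50) == 1.0

    def test_single_subject_event(self):
        curve = km_estimate([1], [True])
        assert curve.at(1) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_explicit_product_limit_on_random_data(self, rng):
        """Estimate equals the independently accumulated product-limit
        formula on 200 random small datasets."""
        for _ in range(200):
            n = int(rng.integers(1, 12))
            t = rng.integers(1, 8, size=n).astype(float)
            d = rng.random(n) < 0.7
            if not d.any():
                continue
            curve = km_estimate(t, d)
            s = 1.0
            expected = []
            for u in sorted(set(t[d])):
                n_i = int((t >= u).sum())
                d_i = int(((t == u) & d).sum())
                s *= 1 - d_i / n_i
                expected.append(s)
            np.testing.assert_allclose(curve.estimate, expected, atol=1e-12)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.integers(1, 20, size=30).astype(float)
        d = rng.random(30) < 0.6
        if not d.any():
            d[0] = True
        kmf = lifelines.KaplanMeierFitter().fit(t, d)
        curve = km_estimate(t, d)
        for u in np.unique(t):
            assert curve.at(u) == pytest.approx(
                float(kmf.survival_function_at_times(u).iloc[0]), abs=1e-10)


class TestGreenwood:
    def test_hand_worked_variance_and_bounds(self):
        """var(5) = 0.75^2 * 1/(4*3) = 0.046875; bounds S +/- z*sqrt(var)."""
        curve = greenwood_ci(km_estimate([5, 10, 10, 15], [True, True, False, True]))
        var5 = 0.75**2 * (1 / (4 * 3))
        assert var5 == pytest.approx(0.046875, abs=1e-15)
        z = norm.ppf(0.975)
        lo, hi = curve.ci_at(5)
        assert lo == pytest.approx(max(0.0, 0.75 - z * np.sqrt(var5)), abs=1e-12)
        assert hi == pytest.approx(min(1.0, 0.75 + z * np.sqrt(var5)), abs=1e-12)

    def test_no_events_means_degenerate_interval(self):
        curve = greenwood_ci(km_estimate([8, 8], [False, False]))
        assert curve.ci_at(4) == (1.0, 1.0)

    def test_bounds_stay_in_unit_interval_on_random_curves(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 15))
            t = rng.integers(1, 10, size=n).astype(float)
            d = rng.random(n) < 0.8
            if not d.any():
                continue
            curve = greenwood_ci(km_estimate(t, d))
            assert (curve.ci_low >= 0).all() and (curve.ci_high <= 1).all()
            assert (curve.ci_low <= curve.estimate + 1e-12).all()
            assert (curve.estimate <= curve.ci_high + 1e-12).all()

    def test_divergent_tail_pinned_to_zero_survival(self):
        curve = greenwood_ci(km_estimate([1, 2], [True, True]))
        lo, hi = curve.ci_at(2)
        assert lo == 0.0 and hi == 0.0  # S = 0 with divergent Greenwood sum


def _ks_exact_enumeration(x, y):
    """Permutation-exact two-sample KS: enumerate all label assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def dstat(xs, ys):
        allv = np.unique(np.concatenate([xs, ys]))
        fx = np.searchsorted(np.sort(xs), allv, side="right") / len(xs)
        fy = np.searchsorted(np.sort(ys), allv, side="right") / len(ys)
        return np.abs(fx - fy).max()

    d_obs = dstat(x, y)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(idx)] = True
        d = dstat(pooled[mask], pooled[~mask])
        count += d >= d_obs - 1e-12
        total += 1
    return d_obs, count / total


def _ranksum_exact_enumeration(x, y):
    """Permutation-exact two-sided rank-sum p via full enumeration."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled)) + 1.0  # no ties assumed
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * m / 2
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return count / total


class TestTwoSampleTests:
    def test_ks_basic_values(self):
        d, p = ks_two_sample([1, 2], [1, 2])
        assert d == 0.0 and p == 1.0
        d, _ = ks_two_sample([1, 2], [3, 4])
        assert d == 1.0
        d, _ = ks_two_sample([1, 3], [2, 4])
        assert d == 0.5

    def test_ks_exact_p_matches_enumeration(self, rng):
        """scipy's exact small-sample path equals brute-force label
        enumeration for min(n, m) <= 8."""
        for _ in range(8):
            n, m = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            x = rng.permutation(100)[:n].astype(float)
            y = rng.permutation(200)[100:100 + m].astype(float)
            d, p = ks_two_sample(x, y)
            d_ref, p_ref = _ks_exact_enumeration(x, y)
            assert d == pytest.approx(d_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_wilcoxon_two_by_two_enumeration(self):
        """x=[1,2] vs y=[3,4]: the most extreme of C(4,2)=6 assignments on
        each side gives two-sided p = 2/6."""
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_wilcoxon_exact_p_matches_enumeration(self, rng):
        for _ in range(6):
            n, m = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            vals = rng.permutation(1000)[: n + m].astype(float)
            x, y = vals[:n], vals[n:]
            _, p = wilcoxon_rank_sum(x, y)
            p_ref = _ranksum_exact_enumeration(x, y)
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_symmetry_and_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = wilcoxon_rank_sum(x, x)
        assert p == 1.0
        y = [2.5, 3.5, 9.0]
        _, pxy = wilcoxon_rank_sum(x, y)
        _, pyx = wilcoxon_rank_sum(y, x)
        assert pxy == pytest.approx(pyx, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [])
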