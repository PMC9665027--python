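"""Endpoint statistics: product-limit survival, Greenwood intervals,
relapse-free fractions, annualized relapse rate and two-sample tests.

The Kaplan–Meier estimator and Greenwood's variance are implemented
directly from their closed forms (they are the package's primary
endpoint machinery); the two-sample Kolmogorov–Smirnov and Wilcoxon
rank-sum tests delegate to scipy, with exact small-sample p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SurvivalCurve", "km_estimate", "greenwood_ci",
    "relapse_free_fraction", "annualized_relapse_rate",
    "ks_two_sample", "wilcoxon_rank_sum", "compare_populations",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate over distinct event times.

    ``estimate[i]`` is S(t) for ``event_times[i] <= t < event_times[i+1]``;
    S(t) = 1 before the first event time.  Confidence bounds are attached
    by :func:`greenwood_ci` and are clipped to [0, 1].
    """
    event_times: np.ndarray   # sorted distinct times with >= 1 event
    at_risk: np.ndarray       # n_i at each event time
    events: np.ndarray        # d_i at each event time
    estimate: np.ndarray      # S(t_i)
    n_subjects: int
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def at(self, t: float) -> float:
        """S(t) as a right-continuous step function."""
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return 1.0 if i < 0 else float(self.estimate[i])

    def ci_at(self, t: float) -> tuple[float, float]:
        if self.ci_low is None or self.ci_high is None:
            raise ValueError("curve has no confidence bounds; run greenwood_ci first")
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        if i < 0:
            return (1.0, 1.0)
        return float(self.ci_low[i]), float(self.ci_high[i])


def km_estimate(times_to_event: Sequence[float],
                observed: Sequence[bool]) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate of the survival function.

    Ties are handled with events processed before censorings at equal
    times (the at-risk set at time t is every subject with time >= t).
    """
    t = np.asarray(times_to_event, dtype=np.float64)
    d = np.asarray(observed, dtype=bool)
    if len(t) == 0:
        raise ValueError("km_estimate requires at least one subject")
    if len(t) != len(d):
        raise ValueError("times and observed flags differ in length")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    ev_times = np.unique(t[d])
    n_i = np.array([(t >= u).sum() for u in ev_times], dtype=np.int64)
    d_i = np.array([(t[d] == u).sum() for u in ev_times], dtype=np.int64)
    est = np.cumprod(1.0 - d_i / n_i)
    return SurvivalCurve(event_times=ev_times, at_risk=n_i, events=d_i,
                         estimate=est, n_subjects=len(t))


def greenwood_ci(curve: SurvivalCurve, alpha: float = 0.05) -> SurvivalCurve:
    """Attach Greenwood 95% (or 1 - alpha) bounds on the plain survival scale.

    ``var(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))``; bounds
    are ``S ± z * sqrt(var)`` clipped to [0, 1].  Where the curve hits
    zero (n_i == d_i) the summand diverges and the bounds are pinned to
    ``[0, S] = [0, 0]`` from that time on.
    """
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    n_i = curve.at_risk.astype(np.float64)
    d_i = curve.events.astype(np.float64)
    with np.errstate(divide="ignore"):
        terms = np.where(n_i > d_i, d_i / (n_i * (n_i - d_i)), np.inf)
    cum = np.cumsum(terms)
    with np.errstate(invalid="ignore"):
        var = curve.estimate**2 * cum
    finite = np.isfinite(cum)
    half = np.where(finite, z * np.sqrt(np.where(finite, var, 0.0)), 0.0)
    lo = np.clip(curve.estimate - half, 0.0, 1.0)
    hi = np.clip(curve.estimate + half, 0.0, 1.0)
    lo[~finite] = 0.0
    hi[~finite] = curve.estimate[~finite]
    return replace(curve, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# trial endpoints (operate on TrialResult-like objects by duck typing)
# ---------------------------------------------------------------------------


def _arm_patients(result, arm: str):
    pats = [p for p in result.patients if p.arm == arm]
    if not pats:
        raise KeyError(f"unknown or empty arm {arm!r}")
    return pats


def relapse_free_fraction(result, arm: str, week: float) -> float:
    """Fraction of the arm's patients with no trial relapse starting on
    or before ``week`` (equals the KM estimate there, as nobody is
    censored before trial end)."""
    pats = _arm_patients(result, arm)
    cutoff = week * 7.0 * result.steps_per_day
    free = sum(1 for p in pats
               if not any(ev.start_time <= cutoff for ev in p.trial_relapses))
    return free / len(pats)


def annualized_relapse_rate(result, arm: str) -> float:
    """Total trial relapse episodes per patient-year in an arm."""
    pats = _arm_patients(result, arm)
    total = sum(len(p.trial_relapses) for p in pats)
    years = len(pats) * result.trial_weeks * 7.0 / 365.25
    return total / years


def arm_survival(result, arm: str, alpha: float = 0.05) -> SurvivalCurve:
    """KM curve (with Greenwood bounds) of time to first trial relapse,
    in weeks; relapse-free patients are administratively censored at
    trial end."""
    pats = _arm_patients(result, arm)
    times, obs = [], []
    spw = 7.0 * result.steps_per_day
    for p in pats:
        if p.trial_relapses:
            times.append(p.trial_relapses[0].start_time / spw)
            obs.append(True)
        else:
            times.append(float(result.trial_weeks))
            obs.append(False)
    return greenwood_ci(km_estimate(times, obs), alpha=alpha)


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test: D = sup |ECDF_x - ECDF_y|.

    Exact p-value for small samples, asymptotic otherwise (scipy's
    'auto' policy)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="auto")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) with midrank ties.

    Exact p by enumeration when both samples are small and tie-free,
    normal approximation with tie correction otherwise."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_populations(popA, popB, variables: Sequence[str]) -> dict:
    """Distributional comparison report between two simulated populations.

    For each immune variable the per-patient trial-long means are
    compared with the KS and Wilcoxon tests; relapse counts are binned
    into the clinically reported {1–2, >=3} classes.
    """
    report: dict = {"version": 1, "variables": {}, "relapse_hist": {}}
    for var in variables:
        a = np.array([p.immune_means[var] for p in popA.patients])
        b = np.array([p.immune_means[var] for p in popB.patients])
        D, p_ks = ks_two_sample(a, b)
        U, p_w = wilcoxon_rank_sum(a, b)
        report["variables"][var] = {
            "median_A": float(np.median(a)), "median_B": float(np.median(b)),
            "ks_D": D, "ks_p": p_ks, "wilcoxon_U": U, "wilcoxon_p": p_w,
        }
    for name, pop in (("A", popA), ("B", popB)):
        counts = [len(p.trial_relapses) + len(p.runin_relapses) for p in pop.patients]
        report["relapse_hist"][name] = {
            "1-2": int(sum(1 for c in counts if 1 <= c <= 2)),
            ">=3": int(sum(1 for c in counts if c >= 3)),
            "0": int(sum(1 for c in counts if c == 0)),
        }
    return report
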