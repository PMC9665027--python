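"""Virtual-trial engine.

Turns a declarative trial configuration into executed per-patient
simulations: candidate digital patients are sampled from the population
base-characteristic distributions, each receives a pre-trial run-in
(immune initialization, EBV trigger, disease history), disease-activity
inclusion criteria are applied at screening, included patients are
randomized into arms at exact target sizes, and every patient is then
simulated through the trial under the arm's treatment plan.  All trial
clocks are synchronized: week 0 is each patient's screening time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .engine import TRAJ_COLUMNS, make_initial_state, run_steps
from .params import EngineParams
from .pathology import (PatientProfile, RelapseEvent, detect_relapses_for,
                        cumulative_oligo_loss, map_characteristics_to_params,
                        trigger_ebv_event, LESION_LOAD, OCB_STATUS, ONSET_AGE)
from .treatments import TreatmentPlan, make_treatment_hook
from . import stats

__all__ = [
    "PopulationSpec", "InclusionCriteria", "Arm", "TrialConfig",
    "PatientRecord", "PopulationResult", "TrialResult",
    "sample_population", "run_preinclusion", "apply_inclusion", "randomize",
    "simulate_population", "run_trial", "patient_seed",
]

DAYS_PER_YEAR = 365.25
_IMMUNE_VARS = ("B", "TH", "IL2", "IFNG", "TGFB", "IgM", "IgG", "IgA")


class ConfigError(ValueError):
    """Invalid trial configuration."""


def _check_dist(name: str, dist: Mapping[str, float], categories: tuple[str, ...]) -> None:
    extra = set(dist) - set(categories)
    if extra:
        raise ConfigError(f"{name}: unknown categories {sorted(extra)}")
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {total}, expected 1")
    if any(v < 0 for v in dist.values()):
        raise ConfigError(f"{name}: negative probability")


@dataclass(frozen=True)
class PopulationSpec:
    """Base-characteristic distributions of a candidate population."""
    lesion_load_dist: Mapping[str, float]
    ocb_dist: Mapping[str, float]
    onset_age_dist: Mapping[str, float]
    disease_duration_years: float = 5.0
    n_candidates: int = 100

    def __post_init__(self):
        _check_dist("lesion_load_dist", self.lesion_load_dist, LESION_LOAD)
        _check_dist("ocb_dist", self.ocb_dist, OCB_STATUS)
        _check_dist("onset_age_dist", self.onset_age_dist, ONSET_AGE)
        if self.n_candidates < 1:
            raise ConfigError("n_candidates must be >= 1")


@dataclass(frozen=True)
class InclusionCriteria:
    """Disease-activity selection rule applied at screening."""
    min_relapses_lookback: int = 1
    lookback_window_days: float = 365.0
    exclusion_window_days: float = 30.0
    require_symptomatic: bool = True

    def __post_init__(self):
        if self.exclusion_window_days > self.lookback_window_days:
            raise ConfigError("exclusion window cannot exceed the lookback window")


@dataclass(frozen=True)
class Arm:
    name: str
    plan: TreatmentPlan
    target_n: int


@dataclass(frozen=True)
class TrialConfig:
    """Full declarative description of one in-silico trial."""
    population: PopulationSpec
    criteria: InclusionCriteria
    arms: Sequence[Arm]
    allocation_ratio: Sequence[int]
    trial_weeks: int
    milestones: Sequence[float] = ()
    runin_years: float | None = None
    seed: int = 0
    expected_inclusion_rate: float = 0.4
    store_trajectories: bool = False

    def __post_init__(self):
        if len(self.arms) != len(self.allocation_ratio):
            raise ConfigError("allocation_ratio must have one entry per arm")
        if any(w > self.trial_weeks for w in self.milestones):
            raise ConfigError("milestones must lie within the trial length")
        if self.trial_weeks <= 0:
            raise ConfigError("empty trial window: trial_weeks must be positive")


@dataclass
class PatientRecord:
    """One simulated digital patient and everything measured on them."""
    profile: PatientProfile
    arm: str | None
    runin_relapses: list[RelapseEvent]
    trial_relapses: list[RelapseEvent]          # times relative to trial step 0
    immune_means: dict[str, float]
    cumulative_loss: int
    time_to_first_trial_relapse: float | None   # weeks, None if relapse-free
    trajectory: np.ndarray | None = None


@dataclass
class PopulationResult:
    """Treatment-naive population run (the Fig.-3-style use case)."""
    patients: list[PatientRecord]
    steps_per_day: int
    runin_years: float
    n_simulated: int

    @property
    def fraction_with_relapse(self) -> float:
        return sum(1 for p in self.patients if p.runin_relapses) / max(1, self.n_simulated)

    @property
    def trial_weeks(self) -> float:    # duck-type for compare_populations
        return self.runin_years * DAYS_PER_YEAR / 7.0


@dataclass
class TrialResult:
    """Executed trial: per-patient records plus per-arm aggregates."""
    patients: list[PatientRecord]
    arm_names: list[str]
    trial_weeks: int
    steps_per_day: int
    milestones: list[float]
    n_sampled: int
    n_included: int
    seed: int
    arm_summaries: dict[str, dict] = field(default_factory=dict)
    arm_plans: dict[str, TreatmentPlan] = field(default_factory=dict)


def patient_seed(trial_seed: int, index: int) -> int:
    """Deterministic per-patient RNG seed derived from (trial seed, index)."""
    return int(np.random.SeedSequence((trial_seed, index)).generate_state(1)[0])


def sample_population(spec: PopulationSpec, seed: int,
                      n: int | None = None, start_index: int = 0) -> list[PatientProfile]:
    """Draw patient profiles i.i.d. from the base-characteristic distributions.

    Each profile's simulation seed is a hash of (population seed, patient
    index), so profiles are reproducible independently of batch size.
    """
    n = spec.n_candidates if n is None else n
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBA5E)))
    # burn a deterministic number of draws so start_index offsets reproduce
    if start_index:
        rng.random(3 * start_index)
    def draw(dist: Mapping[str, float], cats: tuple[str, ...]) -> list[str]:
        p = np.array([dist.get(c, 0.0) for c in cats])
        return [cats[i] for i in rng.choice(len(cats), size=n, p=p)]
    lesion = draw(spec.lesion_load_dist, LESION_LOAD)
    ocb = draw(spec.ocb_dist, OCB_STATUS)
    onset = draw(spec.onset_age_dist, ONSET_AGE)
    return [
        PatientProfile(
            lesion_load=lesion[i], ocb_status=ocb[i], onset_age=onset[i],
            disease_duration_years=spec.disease_duration_years,
            seed=patient_seed(seed, start_index + i),
        )
        for i in range(n)
    ]


def run_preinclusion(profile: PatientProfile, runin_years: float | None = None,
                     calibration: Mapping | None = None):
    """Simulate one patient's pre-trial disease history.

    Initializes the immune system at homeostasis, draws the EBV trigger
    time uniformly within the first simulated year, runs
    ``runin_years`` (default: the profile's disease duration) and
    returns ``(terminal state, relapse events, trajectory)``.
    """
    overrides = map_characteristics_to_params(profile, calibration)
    params = EngineParams.with_overrides(overrides)
    if runin_years is None:
        runin_years = profile.disease_duration_years
    if runin_years <= 0:
        raise ValueError("runin_years must be positive")
    rng = np.random.default_rng(profile.seed)
    state = make_initial_state(params, rng)
    n_steps = int(round(runin_years * DAYS_PER_YEAR * params.steps_per_day))
    if params.ebv_enabled:
        t_event = int(rng.integers(0, params.days(params.ebv_window_days)))
        def hook(st, i, _t=t_event):
            if i == _t and not st.ebv_fired:
                trigger_ebv_event(st, i)
    else:
        hook = None
    traj = run_steps(state, n_steps, hook=hook)
    events = detect_relapses_for(traj[:, TRAJ_COLUMNS.index("oligo")], params)
    return state, events, traj


def apply_inclusion(history: Sequence[RelapseEvent], criteria: InclusionCriteria,
                    t_screen: int, steps_per_day: int = 1) -> bool:
    """Disease-activity inclusion decision at screening time ``t_screen``.

    A relapse counts as inside a window when its episode *start* falls
    inside.  Requires >= ``min_relapses_lookback`` starts in the
    lookback window, none in the terminal exclusion window, and (if
    ``require_symptomatic``) at least one relapse ever.
    """
    starts = np.array([ev.start_time for ev in history], dtype=float)
    starts = starts[starts <= t_screen]
    look = t_screen - criteria.lookback_window_days * steps_per_day
    excl = t_screen - criteria.exclusion_window_days * steps_per_day
    n_look = int((starts >= look).sum())
    n_excl = int((starts >= excl).sum())
    if criteria.require_symptomatic and len(starts) == 0:
        return False
    return n_look >= criteria.min_relapses_lookback and n_excl == 0


def randomize(included: Sequence[PatientProfile], arms: Sequence[Arm],
              ratio: Sequence[int], seed: int) -> dict[str, list[PatientProfile]]:
    """Permuted-block randomization to exact arm target sizes.

    Patients are first put in a canonical order (by profile seed) so the
    assignment depends only on (patients, seed), not on input ordering.
    """
    targets = {a.name: a.target_n for a in arms}
    need = sum(targets.values())
    if len(included) < need:
        raise ValueError(
            f"insufficient included patients: need {need}, have {len(included)} "
            f"(short by {need - len(included)})")
    ordered = sorted(included, key=lambda p: p.seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA110C)))
    ordered = [ordered[i] for i in rng.permutation(len(ordered))]
    block = [a.name for a, r in zip(arms, ratio) for _ in range(r)]
    out: dict[str, list[PatientProfile]] = {a.name: [] for a in arms}
    it = iter(ordered)
    while any(len(out[a.name]) < targets[a.name] for a in arms):
        for name in (block[j] for j in rng.permutation(len(block))):
            if len(out[name]) < targets[name]:
                out[name].append(next(it))
    return out


def _immune_means(traj: np.ndarray) -> dict[str, float]:
    return {v: float(traj[:, TRAJ_COLUMNS.index(v)].mean()) for v in _IMMUNE_VARS}


def _runin_map(profiles, runin_years, calibration, jobs):
    """Run pre-inclusion histories, optionally across worker processes.

    Each patient owns an independent RNG stream, so the result list is
    identical for any ``jobs`` value and any scheduling order.
    """
    if jobs and jobs > 1:
        from joblib import Parallel, delayed
        return Parallel(n_jobs=jobs)(
            delayed(run_preinclusion)(p, runin_years, calibration) for p in profiles)
    return [run_preinclusion(p, runin_years, calibration) for p in profiles]


def simulate_population(spec: PopulationSpec, seed: int,
                        calibration: Mapping | None = None,
                        keep_all: bool = True, jobs: int = 1) -> PopulationResult:
    """Run a treatment-naive population through its disease history.

    Every candidate is simulated for the spec's disease duration; the
    returned records carry relapse histories and trial-long immune-
    variable means.  ``fraction_with_relapse`` is the share of simulated
    candidates with at least one relapse (the population inclusion
    fraction of the symptomatic-selection use case).
    """
    profiles = sample_population(spec, seed)
    records = []
    outcomes = _runin_map(profiles, None, calibration, jobs)
    for prof, (_, events, traj) in zip(profiles, outcomes):
        if events or keep_all:
            records.append(PatientRecord(
                profile=prof, arm=None, runin_relapses=events, trial_relapses=[],
                immune_means=_immune_means(traj),
                cumulative_loss=cumulative_oligo_loss(events),
                time_to_first_trial_relapse=None))
    p0 = records[0].profile if records else profiles[0]
    spd = EngineParams.with_overrides(map_characteristics_to_params(p0)).steps_per_day
    return PopulationResult(patients=records, steps_per_day=spd,
                            runin_years=spec.disease_duration_years,
                            n_simulated=len(profiles))


def run_trial(config: TrialConfig, calibration: Mapping | None = None,
              progress=None, jobs: int = 1) -> TrialResult:
    """Execute the full trial pipeline (Fig.-1-style workflow).

    Candidates are sampled in batches (modestly oversampled against the
    expected inclusion rate) until every arm target can be met; whole
    batches are always processed so the included set does not depend on
    worker scheduling.  No patient is censored before trial end.
    """
    runin_years = (config.runin_years if config.runin_years is not None
                   else config.population.disease_duration_years)
    need = sum(a.target_n for a in config.arms)
    included: list[tuple[PatientProfile, Any, list[RelapseEvent], np.ndarray]] = []
    n_sampled = 0
    max_candidates = max(50, 25 * need)
    while len(included) < need:
        batch = math.ceil(
            (need - len(included)) / config.expected_inclusion_rate * 1.15)
        batch = min(batch, max_candidates - n_sampled)
        if batch <= 0:
            raise RuntimeError(
                f"inclusion stalled: {len(included)}/{need} included after "
                f"{n_sampled} candidates")
        profiles = sample_population(config.population, config.seed,
                                     n=batch, start_index=n_sampled)
        n_sampled += batch
        outcomes = _runin_map(profiles, runin_years, calibration, jobs)
        for prof, (state, events, traj) in zip(profiles, outcomes):
            if apply_inclusion(events, config.criteria, state.time,
                               state.params.steps_per_day):
                oligo_runin = traj[:, TRAJ_COLUMNS.index("oligo")].copy()
                included.append((prof, state, events, oligo_runin))
        if progress is not None:
            progress(n_sampled, len(included))

    assignment = randomize([p for p, *_ in included], config.arms,
                           config.allocation_ratio, config.seed)
    by_seed = {p.seed: (p, st, ev, tr) for p, st, ev, tr in included}

    records: list[PatientRecord] = []
    for arm in config.arms:
        hook_factory = lambda: make_treatment_hook(arm.plan, config.trial_weeks)
        for prof in assignment[arm.name]:
            _, state, runin_events, oligo_runin = by_seed[prof.seed]
            params = state.params
            n_steps = int(round(config.trial_weeks * 7 * params.steps_per_day))
            runin_steps = state.time
            traj = run_steps(state, n_steps, hook=hook_factory())
            full_oligo = np.concatenate([oligo_runin, traj[:, TRAJ_COLUMNS.index("oligo")]])
            all_events = detect_relapses_for(full_oligo, params)
            trial_events = [
                RelapseEvent(ev.start_time - runin_steps, ev.end_time - runin_steps,
                             ev.magnitude)
                for ev in all_events if ev.start_time >= runin_steps]
            ttfr = (trial_events[0].start_time / (7.0 * params.steps_per_day)
                    if trial_events else None)
            records.append(PatientRecord(
                profile=prof, arm=arm.name,
                runin_relapses=runin_events, trial_relapses=trial_events,
                immune_means=_immune_means(traj),
                cumulative_loss=cumulative_oligo_loss(trial_events),
                time_to_first_trial_relapse=ttfr,
                trajectory=traj if config.store_trajectories else None))

    spd = included[0][1].params.steps_per_day
    result = TrialResult(
        patients=records, arm_names=[a.name for a in config.arms],
        trial_weeks=config.trial_weeks, steps_per_day=spd,
        milestones=list(config.milestones),
        n_sampled=n_sampled, n_included=len(included), seed=config.seed,
        arm_plans={a.name: a.plan for a in config.arms})
    for name in result.arm_names:
        curve = stats.arm_survival(result, name)
        summary = {
            "n": sum(1 for p in records if p.arm == name),
            "annualized_relapse_rate": stats.annualized_relapse_rate(result, name),
            "relapse_free": {
                str(w): stats.relapse_free_fraction(result, name, w)
                for w in config.milestones},
            "immune_means": {
                v: float(np.mean([p.immune_means[v] for p in records if p.arm == name]))
                for v in _IMMUNE_VARS},
            "cumulative_loss_mean": float(np.mean(
                [p.cumulative_loss for p in records if p.arm == name])),
            "km_week104_ci": curve.ci_at(104.0) if config.trial_weeks >= 104 else None,
        }
        result.arm_summaries[name] = summary
    return result
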