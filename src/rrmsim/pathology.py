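"""RRMS disease layer.

White-matter oligodendrocytes carry a shared self-epitope.  An
Epstein–Barr-virus-like infection event introduces a viral epitope a few
bits away from that self-epitope (molecular mimicry); the ensuing
anti-viral response expands cross-reactive clones which, after
trafficking into the white matter, kill oligodendrocytes.  Episodes of
oligodendrocyte loss above a threshold are the model's relapses.

Patient base characteristics (lesion load, oligoclonal band status, age
of onset) enter the model exclusively through the shipped calibration
table, which maps each of the 12 category combinations onto engine
parameter overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .agents import CellState, CellType, Compartment
from .engine import SimState
from .receptors import binds_many

__all__ = [
    "LESION_LOAD", "OCB_STATUS", "ONSET_AGE",
    "RelapseEvent", "PatientProfile", "CalibrationError",
    "load_calibration_table", "map_characteristics_to_params",
    "trigger_ebv_event", "autoimmune_attack",
    "detect_relapses", "detect_relapses_for", "cumulative_oligo_loss",
]

LESION_LOAD = ("HIGH", "LOW_MEDIUM")
OCB_STATUS = ("PRESENT", "ABSENT")
ONSET_AGE = ("18-29", "30-39", "40-49")


class CalibrationError(KeyError):
    """Calibration table does not cover a base-characteristic combination."""


@dataclass(frozen=True, order=True)
class RelapseEvent:
    """One episode of autoimmune oligodendrocyte loss."""
    start_time: int     # timestep the episode opened
    end_time: int       # timestep of the last loss in the episode
    magnitude: int      # oligodendrocytes lost peak-to-trough

    def __post_init__(self):
        if self.end_time < self.start_time:
            raise ValueError("relapse end_time precedes start_time")


@dataclass(frozen=True)
class PatientProfile:
    """Base characteristics + seed defining one digital patient."""
    lesion_load: str
    ocb_status: str
    onset_age: str
    disease_duration_years: float = 5.0
    seed: int = 0
    extra_overrides: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.lesion_load not in LESION_LOAD:
            raise ValueError(f"lesion_load must be one of {LESION_LOAD}")
        if self.ocb_status not in OCB_STATUS:
            raise ValueError(f"ocb_status must be one of {OCB_STATUS}")
        if self.onset_age not in ONSET_AGE:
            raise ValueError(f"onset_age must be one of {ONSET_AGE}")
        if self.disease_duration_years < 0:
            raise ValueError("disease_duration_years must be >= 0")

    @property
    def combo_key(self) -> str:
        return f"{self.lesion_load}|{self.ocb_status}|{self.onset_age}"


# ---------------------------------------------------------------------------
# calibration table
# ---------------------------------------------------------------------------

_TABLE_CACHE: dict[str, dict] | None = None


def load_calibration_table(path: str | None = None) -> dict[str, dict]:
    """Load a calibration table (default: the shipped versioned table).

    The table must cover all 12 lesion x OCB x onset-age combinations.
    """
    global _TABLE_CACHE
    if path is None and _TABLE_CACHE is not None:
        return _TABLE_CACHE
    if path is None:
        ref = resources.files("rrmsim.data").joinpath("calibration.yaml")
        with ref.open("r") as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    combos = raw["combos"]
    missing = [f"{l}|{o}|{a}" for l in LESION_LOAD for o in OCB_STATUS
               for a in ONSET_AGE if f"{l}|{o}|{a}" not in combos]
    if missing:
        raise CalibrationError(f"calibration table missing combinations: {missing}")
    if path is None:
        _TABLE_CACHE = combos
    return combos


def map_characteristics_to_params(
    profile: PatientProfile,
    calibration: Mapping[str, Mapping[str, Any]] | None = None,
) -> dict[str, Any]:
    """Resolve a profile's base characteristics into engine parameter overrides.

    Deterministic: the same profile always yields the same overrides.
    Profile-level ``extra_overrides`` win over the calibration entry.
    """
    table = calibration if calibration is not None else load_calibration_table()
    try:
        overrides = dict(table[profile.combo_key])
    except KeyError as exc:
        raise CalibrationError(
            f"no calibration entry for combination {profile.combo_key!r}"
        ) from exc
    overrides.update(profile.extra_overrides)
    return overrides


# ---------------------------------------------------------------------------
# EBV trigger and autoimmune attack
# ---------------------------------------------------------------------------


def trigger_ebv_event(state: SimState, t_event: int) -> SimState:
    """Fire the (one-shot) EBV-like infection in the periphery.

    The viral epitope is the oligodendrocyte self-epitope with
    ``mimicry_flips`` random bits flipped (``< 0`` draws an unrelated
    random epitope), so part of the anti-viral repertoire cross-reacts
    with self.
    """
    if state.ebv_fired:
        raise RuntimeError("EBV event already triggered in this simulation")
    if t_event < 0:
        raise ValueError("t_event must be a non-negative timestep")
    p = state.params
    if p.mimicry_flips < 0:
        antigen = int(state.rng.integers(0, 1 << p.receptor_length))
    else:
        antigen = int(p.self_antigen)
        for _ in range(int(p.mimicry_flips)):
            antigen ^= 1 << int(state.rng.integers(0, p.receptor_length))
    state.viral_antigen = antigen
    state.viral_load = p.viral_init
    state.ebv_fired = True
    idx = np.flatnonzero(state.pool.alive)
    state.pool.binds_viral[idx] = binds_many(
        state.pool.receptor[idx], antigen, p.receptor_length, p.bind_threshold)
    return state


def autoimmune_attack(state: SimState) -> SimState:
    """Kill oligodendrocytes under co-located, self-binding effectors.

    Runs inside the interaction phase of every step.  Each activated TH
    or CTL in the white matter that binds the self-epitope and shares a
    site with a live oligodendrocyte kills one with the configured
    per-step probability; kills feed the myelin-debris pool that drives
    continued self-antigen presentation.  Debris decays here as well.
    """
    p, pool, rng = state.params, state.pool, state.rng
    state.debris *= p.debris_decay
    if state.debris < 1e-6:
        state.debris = 0.0
    wm = int(Compartment.WHITE_MATTER)
    if not (pool.alive & (pool.comp == wm)).any():
        return state
    if not state.oligo_alive.any():
        return state
    eff = (pool.alive & (pool.comp == wm)
           & ((pool.state == int(CellState.ACTIVATED))
              | (pool.state == int(CellState.DUPLICATING)))
           & pool.binds_self
           & ((pool.ctype == int(CellType.CTL)) | (pool.ctype == int(CellType.TH))))
    idx = np.flatnonzero(eff)
    if len(idx) == 0:
        return state
    idx = idx[state.oligo_per_site[pool.site[idx]] > 0]
    if len(idx) == 0:
        return state
    pk = np.where(pool.ctype[idx] == CellType.CTL, p.p_kill_ctl, p.p_kill_th)
    killers = idx[rng.random(len(idx)) < pk]
    if len(killers) == 0:
        return state
    kills = 0
    for s in np.unique(pool.site[killers]):
        n_att = int((pool.site[killers] == s).sum())
        live = np.flatnonzero(state.oligo_alive & (state.oligo_site == s))
        if len(live) == 0:
            continue
        n_kill = min(n_att, len(live))
        victims = rng.choice(live, size=n_kill, replace=False)
        state.oligo_alive[victims] = False
        state.oligo_per_site[s] -= n_kill
        kills += n_kill
    if kills:
        state.kills_this_step += kills
        state.debris += p.debris_per_kill * kills
    return state


# ---------------------------------------------------------------------------
# relapse detection
# ---------------------------------------------------------------------------


def detect_relapses(
    oligo_trajectory: Sequence[float] | np.ndarray,
    baseline: float,
    theta: float,
    window: int,
    min_gap: int,
) -> list[RelapseEvent]:
    """Extract relapse episodes from an oligodendrocyte count trajectory.

    An episode opens at the first step where the count has fallen by at
    least ``theta * baseline`` within the trailing ``window`` steps,
    tracks the running trough, and closes once no further loss occurs
    for ``min_gap`` steps.  Episodes closer than ``min_gap`` are merged.
    The detector is a pure function of its inputs and is insensitive to
    a flat tail appended after the last episode.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie strictly between 0 and 1")
    counts = np.asarray(oligo_trajectory, dtype=np.float64)
    n = len(counts)
    if n == 0:
        return []
    thr = theta * baseline
    trail_max = _trailing_max(counts, window)
    openable = (trail_max - counts) >= thr
    events: list[RelapseEvent] = []
    t = 0
    while t < n:
        rel = np.argmax(openable[t:])
        if not openable[t:][rel]:
            break
        s = t + int(rel)
        peak = trail_max[s]
        min_c = counts[s]
        last_loss = s
        u = s + 1
        while u < n:
            if counts[u] < min_c:
                min_c = counts[u]
                last_loss = u
            if u - last_loss >= min_gap:
                break
            u += 1
        events.append(RelapseEvent(start_time=s, end_time=int(last_loss),
                                   magnitude=int(round(peak - min_c))))
        t = max(u, s + 1)
    return _merge_close(events, min_gap)


def _trailing_max(counts: np.ndarray, window: int) -> np.ndarray:
    """max over counts[max(0, t-window) : t+1] for each t."""
    from numpy.lib.stride_tricks import sliding_window_view

    padded = np.concatenate([np.full(window, counts[0]), counts])
    return sliding_window_view(padded, window + 1).max(axis=1)


def _merge_close(events: list[RelapseEvent], min_gap: int) -> list[RelapseEvent]:
    if not events:
        return []
    merged = [events[0]]
    for ev in events[1:]:
        prev = merged[-1]
        if ev.start_time - prev.end_time < min_gap:
            merged[-1] = RelapseEvent(start_time=prev.start_time,
                                      end_time=ev.end_time,
                                      magnitude=prev.magnitude + ev.magnitude)
        else:
            merged.append(ev)
    return merged


def detect_relapses_for(oligo_trajectory: np.ndarray, params) -> list[RelapseEvent]:
    """Relapse detection with a parameter set's shipped thresholds."""
    return detect_relapses(
        oligo_trajectory,
        baseline=params.n_oligo,
        theta=params.relapse_theta,
        window=params.days(params.relapse_window_days),
        min_gap=params.days(params.relapse_min_gap_days),
    )


def cumulative_oligo_loss(events: Sequence[RelapseEvent]) -> int:
    """Total oligodendrocytes lost across all relapse episodes."""
    return int(sum(ev.magnitude for ev in events))
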