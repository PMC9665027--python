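"""Disease-modifying treatments: dosing schedules and mechanisms of action.

Each drug is represented by a unitless effect envelope in [0, 1] that
jumps to its (dose-saturating) peak at each administration and decays
exponentially with a drug-specific half-life in between.  The envelope
perturbs engine parameters or agent populations — never the clinical
endpoints directly:

* natalizumab   — blocks leukocyte migration into the white matter;
* ocrelizumab   — anti-CD20 depletion of circulating B cells;
* IFNβ-1a       — damps lymphocyte activation/proliferation and shifts
                  the cytokine milieu toward TGF-β;
* teriflunomide — inhibits proliferation of activated lymphocytes.

Only natalizumab's mechanism (migration blockade) is prescribed by the
modelled system; the other three are the field-standard mechanisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import SimState

__all__ = [
    "DRUGS", "TreatmentPlan", "DrugEffectState", "DRUG_PD",
    "schedule_doses", "update_effect", "effect_at",
    "apply_natalizumab", "apply_ocrelizumab", "apply_ifnb1a",
    "apply_teriflunomide", "apply_drug", "NATALIZUMAB_AFFIRM",
]

DRUGS = ("NONE", "IFNB1A", "TERIFLUNOMIDE", "NATALIZUMAB", "OCRELIZUMAB")

#: Pharmacodynamic constants per drug: effect half-life (days) and the dose
#: (mg) at which the administration peak reaches 1 - 1/e of saturation.
DRUG_PD = {
    "IFNB1A": {"half_life_days": 5.0, "dose_scale_mg": 0.006},
    "TERIFLUNOMIDE": {"half_life_days": 14.0, "dose_scale_mg": 2.8},
    "NATALIZUMAB": {"half_life_days": 120.0, "dose_scale_mg": 60.0},
    "OCRELIZUMAB": {"half_life_days": 60.0, "dose_scale_mg": 120.0},
}

#: Maximal mechanistic effect sizes (per-step scale factors at effect = 1).
E_MAX_NATALIZUMAB = 1.0    # fractional reduction of periphery->WM migration
K_OCRELIZUMAB = 0.5        # per-step B-cell kill probability
K_IFNB1A = 0.5             # fractional damping of activation/duplication
G_IFNB1A = 0.5             # fractional boost of TGF-beta secretion
K_TERIFLUNOMIDE = 0.6      # fractional damping of activated-cell duplication


@dataclass(frozen=True)
class TreatmentPlan:
    """One arm's treatment: drug, dose, interval and trial-relative window."""
    drug: str = "NONE"
    dose_mg: float = 0.0
    interval_days: float = 0.0
    start_week: float = 0.0
    end_week: float = 0.0

    def __post_init__(self):
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}; choose from {DRUGS}")
        if self.drug != "NONE" and self.interval_days <= 0:
            raise ValueError("interval_days must be positive for an active drug")
        if self.end_week < self.start_week:
            raise ValueError("end_week must be >= start_week")

    @property
    def peak_effect(self) -> float:
        if self.drug == "NONE":
            return 0.0
        scale = DRUG_PD[self.drug]["dose_scale_mg"]
        return 1.0 - math.exp(-self.dose_mg / scale)


#: The AFFIRM regimen: 300 mg natalizumab every 4 weeks for 104 weeks.
NATALIZUMAB_AFFIRM = TreatmentPlan(
    drug="NATALIZUMAB", dose_mg=300.0, interval_days=28.0,
    start_week=0.0, end_week=104.0,
)


def schedule_doses(plan: TreatmentPlan, trial_weeks: float,
                   steps_per_day: int = 1) -> list[int]:
    """Administration timesteps for a plan over a trial.

    Doses fall at ``start_week`` and then every ``interval_days`` while
    strictly inside the treatment window ``[start_week, end_week)``
    (clipped to the trial length): a 28-day interval over a 104-week
    window yields 26 administrations.
    """
    if plan.drug == "NONE":
        return []
    end_day = min(plan.end_week, trial_weeks) * 7.0
    out: list[int] = []
    t_day = plan.start_week * 7.0
    while t_day < end_day:
        out.append(int(round(t_day * steps_per_day)))
        t_day += plan.interval_days
    return out


@dataclass
class DrugEffectState:
    """Book-keeping of one drug's current effect level."""
    drug: str = "NONE"
    effect: float = 0.0
    last_admin: int | None = None
    peak: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")


def effect_at(t: int, administrations: list[int], half_life_days: float,
              peak: float = 1.0, steps_per_day: int = 1) -> float:
    """Effect envelope at timestep ``t``: ``peak`` at each administration,
    exponential decay with the given half-life in between, 0 before the
    first dose."""
    past = [a for a in administrations if a <= t]
    if not past:
        return 0.0
    dt_days = (t - past[-1]) / steps_per_day
    return peak * 0.5 ** (dt_days / half_life_days)


def update_effect(effect_state: DrugEffectState, t: int,
                  administrations: list[int],
                  steps_per_day: int = 1) -> DrugEffectState:
    """Advance a drug-effect envelope to timestep ``t`` (administrations
    must be sorted)."""
    if effect_state.drug == "NONE":
        return effect_state
    hl = DRUG_PD[effect_state.drug]["half_life_days"]
    past = [a for a in administrations if a <= t]
    effect_state.last_admin = past[-1] if past else None
    effect_state.effect = effect_at(t, administrations, hl,
                                    peak=effect_state.peak,
                                    steps_per_day=steps_per_day)
    return effect_state


# ---------------------------------------------------------------------------
# mechanisms of action (each resets its own modifier from the effect level,
# so effect = 0 restores the treatment-naive engine exactly)
# ---------------------------------------------------------------------------


def _check_effect(effect: float) -> None:
    if not 0.0 <= effect <= 1.0:
        raise ValueError(f"effect must lie in [0, 1], got {effect}")


def apply_natalizumab(state: SimState, effect: float) -> SimState:
    """Scale periphery -> white-matter migration by ``1 - effect * e_max``."""
    _check_effect(effect)
    state.modifiers["mig_factor"] = 1.0 - effect * E_MAX_NATALIZUMAB
    return state


def apply_ocrelizumab(state: SimState, effect: float) -> SimState:
    """Deplete circulating B cells (not plasma cells) with per-step
    probability ``effect * k_ocr``; antibody titers are untouched."""
    _check_effect(effect)
    state.modifiers["b_kill_prob"] = effect * K_OCRELIZUMAB
    return state


def apply_ifnb1a(state: SimState, effect: float) -> SimState:
    """Damp lymphocyte activation and duplication by ``1 - effect * k_ifn``
    and raise TGF-β secretion by ``1 + effect * g_ifn``."""
    _check_effect(effect)
    state.modifiers["act_factor"] = 1.0 - effect * K_IFNB1A
    state.modifiers["dup_factor"] = 1.0 - effect * K_IFNB1A
    state.modifiers["tgfb_factor"] = 1.0 + effect * G_IFNB1A
    return state


def apply_teriflunomide(state: SimState, effect: float) -> SimState:
    """Damp duplication of activated lymphocytes by ``1 - effect * k_ter``."""
    _check_effect(effect)
    state.modifiers["dup_factor_activated"] = 1.0 - effect * K_TERIFLUNOMIDE
    return state


_APPLY = {
    "NATALIZUMAB": apply_natalizumab,
    "OCRELIZUMAB": apply_ocrelizumab,
    "IFNB1A": apply_ifnb1a,
    "TERIFLUNOMIDE": apply_teriflunomide,
}


def apply_drug(state: SimState, drug: str, effect: float) -> SimState:
    """Dispatch to the drug's mechanism; ``NONE`` is a no-op."""
    if drug == "NONE":
        return state
    return _APPLY[drug](state, effect)


def make_treatment_hook(plan: TreatmentPlan, trial_weeks: float,
                        steps_per_day: int = 1):
    """Per-step hook for :func:`rrmsim.engine.run_steps` applying a plan.

    The hook index ``i`` counts steps from trial week 0.
    """
    if plan.drug == "NONE":
        return None
    admins = schedule_doses(plan, trial_weeks, steps_per_day)
    hl = DRUG_PD[plan.drug]["half_life_days"]
    peak = plan.peak_effect
    admin_arr = admins

    def hook(state: SimState, i: int) -> None:
        eff = effect_at(i, admin_arr, hl, peak=peak, steps_per_day=steps_per_day)
        apply_drug(state, plan.drug, eff)

    return hook
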