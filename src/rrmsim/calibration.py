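"""Calibration harness for the base-characteristic mapping.

The disease layer's quantitative anchors are population statistics (the
share of 5-year treatment-naive histories with at least one relapse, the
1–9 relapse-count range of symptomatic patients, and the untreated-arm
relapse-free fraction at 104 weeks), not published rate constants.  This
module expresses the 12-combination calibration table through a small
set of interpretable factors, scores candidate tables against those
statistics on batch simulations, and runs a seeded random search.  The
winning table ships as ``data/calibration.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import yaml

from .params import load_default_params
from .pathology import LESION_LOAD, OCB_STATUS, ONSET_AGE

__all__ = ["CalibrationFactors", "build_table", "write_table",
           "evaluate_calibration", "random_search"]

#: Ordered onset categories, youngest first.
_AGE_RANK = {"18-29": 1.0, "30-39": 0.0, "40-49": -1.0}


@dataclass(frozen=True)
class CalibrationFactors:
    """Low-dimensional parameterization of the calibration table.

    p_auto_base        autoreactive-receptor bias for LOW_MEDIUM lesion load
    lesion_mult        multiplier on p_auto for HIGH lesion load (>= 1)
    kill_mult_high     multiplier on effector kill rates for HIGH lesion load
    age_gradient       fractional boost of B/TH set-points per age rank
                       (younger onset -> more vigorous adaptive compartment)
    treg_gradient      fractional change of the TREG set-point per age rank
    present_self_max   APC self-epitope presentation ceiling (chronic phase)
    """
    p_auto_base: float = 0.0007
    lesion_mult: float = 1.3
    kill_mult_high: float = 1.05
    age_gradient: float = 0.18
    treg_gradient: float = 0.05
    present_self_max: float = 0.138
    death_plasma_ocb: float = 0.006
    death_plasma_no_ocb: float = 0.012


def build_table(factors: CalibrationFactors) -> dict[str, dict]:
    """Resolve the factors into explicit overrides for all 12 combinations."""
    base = load_default_params()
    combos: dict[str, dict] = {}
    for lesion in LESION_LOAD:
        for ocb in OCB_STATUS:
            for age in ONSET_AGE:
                rank = _AGE_RANK[age]
                high = lesion == "HIGH"
                entry = {
                    "p_auto": round(factors.p_auto_base
                                    * (factors.lesion_mult if high else 1.0), 6),
                    "p_kill_ctl": round(base["p_kill_ctl"]
                                        * (factors.kill_mult_high if high else 1.0), 4),
                    "p_kill_th": round(base["p_kill_th"]
                                       * (factors.kill_mult_high if high else 1.0), 4),
                    "setpoint_B": int(round(base["setpoint_B"]
                                            * (1 + factors.age_gradient * rank))),
                    "setpoint_TH": int(round(base["setpoint_TH"]
                                             * (1 + factors.age_gradient * rank))),
                    "setpoint_TREG": int(round(base["setpoint_TREG"]
                                               * (1 + factors.treg_gradient * rank))),
                    "death_plasma": (factors.death_plasma_ocb if ocb == "PRESENT"
                                     else factors.death_plasma_no_ocb),
                    "p_present_self_max": factors.present_self_max,
                }
                combos[f"{lesion}|{ocb}|{age}"] = entry
    return combos


def write_table(factors: CalibrationFactors, path: str, version: int = 1) -> None:
    doc = {
        "version": version,
        "factors": asdict(factors),
        "combos": build_table(factors),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _population_specs():
    from .trial import PopulationSpec
    pop1 = PopulationSpec(
        lesion_load_dist={"HIGH": 1.0},
        ocb_dist={"PRESENT": 0.9, "ABSENT": 0.1},
        onset_age_dist={"30-39": 0.5, "40-49": 0.5},
        disease_duration_years=5.0, n_candidates=1)
    pop2 = PopulationSpec(
        lesion_load_dist={"LOW_MEDIUM": 1.0},
        ocb_dist={"PRESENT": 0.9, "ABSENT": 0.1},
        onset_age_dist={"18-29": 1.0},
        disease_duration_years=5.0, n_candidates=1)
    return pop1, pop2


def evaluate_calibration(table: Mapping[str, dict], n: int, seed: int,
                         with_trial: bool = False, trial_n: tuple[int, int] = (20, 20)
                         ) -> dict:
    """Population statistics of a candidate table at sample size ``n``."""
    from . import trial as trial_mod
    from .trial import PopulationSpec  # noqa: F401  (spec construction above)

    pop1_spec, pop2_spec = _population_specs()
    pop1_spec = PopulationSpec(**{**asdict_spec(pop1_spec), "n_candidates": n})
    pop2_spec = PopulationSpec(**{**asdict_spec(pop2_spec), "n_candidates": n})
    res1 = trial_mod.simulate_population(pop1_spec, seed, calibration=table)
    res2 = trial_mod.simulate_population(pop2_spec, seed + 1, calibration=table)
    counts = [len(p.runin_relapses) for p in res1.patients + res2.patients
              if p.runin_relapses]
    out = {
        "pop1_fraction": res1.fraction_with_relapse,
        "pop2_fraction": res2.fraction_with_relapse,
        "relapse_count_min": int(min(counts)) if counts else 0,
        "relapse_count_max": int(max(counts)) if counts else 0,
    }
    if with_trial:
        out.update(affirm_statistics(table, trial_n, seed))
    return out


def asdict_spec(spec) -> dict:
    return {
        "lesion_load_dist": dict(spec.lesion_load_dist),
        "ocb_dist": dict(spec.ocb_dist),
        "onset_age_dist": dict(spec.onset_age_dist),
        "disease_duration_years": spec.disease_duration_years,
        "n_candidates": spec.n_candidates,
    }


def affirm_trial_config(seed: int, n_treated: int = 80, n_control: int = 40):
    """The natalizumab historical-trial recreation preset, as code."""
    from .trial import Arm, InclusionCriteria, PopulationSpec, TrialConfig
    from .treatments import NATALIZUMAB_AFFIRM, TreatmentPlan
    population = PopulationSpec(
        lesion_load_dist={"HIGH": 1.0},
        ocb_dist={"PRESENT": 1.0},
        onset_age_dist={"18-29": 0.494, "30-39": 0.362, "40-49": 0.144},
        disease_duration_years=5.0,
        n_candidates=max(1, int((n_treated + n_control) / 0.4)))
    return TrialConfig(
        population=population,
        criteria=InclusionCriteria(min_relapses_lookback=1,
                                   lookback_window_days=365.0,
                                   exclusion_window_days=30.0,
                                   require_symptomatic=True),
        arms=[Arm("natalizumab", NATALIZUMAB_AFFIRM, n_treated),
              Arm("control", TreatmentPlan(), n_control)],
        allocation_ratio=[2, 1],
        trial_weeks=116, milestones=[104.0],
        runin_years=5.0, seed=seed,
        expected_inclusion_rate=0.18)


def affirm_statistics(table: Mapping[str, dict], trial_n: tuple[int, int],
                      seed: int) -> dict:
    from . import trial as trial_mod
    cfg = affirm_trial_config(seed, n_treated=trial_n[0], n_control=trial_n[1])
    res = trial_mod.run_trial(cfg, calibration=table)
    return {
        "control_rf104": res.arm_summaries["control"]["relapse_free"]["104.0"],
        "natalizumab_rf104": res.arm_summaries["natalizumab"]["relapse_free"]["104.0"],
        "inclusion_rate": res.n_included / res.n_sampled,
    }


def score(metrics: Mapping[str, float]) -> float:
    """Weighted squared distance from the documented population targets."""
    s = ((metrics["pop1_fraction"] - 0.58) ** 2
         + (metrics["pop2_fraction"] - 0.59) ** 2)
    if "control_rf104" in metrics:
        s += 2.0 * (metrics["control_rf104"] - 0.40) ** 2
        s += 2.0 * max(0.0, 0.90 - metrics["natalizumab_rf104"]) ** 2
    # symptomatic relapse counts should span roughly 1..9 over five years
    if metrics["relapse_count_max"] > 9:
        s += 0.01 * (metrics["relapse_count_max"] - 9) ** 2
    return float(s)


def random_search(n_iter: int, n_patients: int, seed: int,
                  base: CalibrationFactors | None = None,
                  with_trial: bool = False, verbose: bool = True):
    """Seeded random search over the calibration factors.

    Samples factors log-uniformly around the incumbent, keeps the best
    score; returns (best factors, best metrics, history).
    """
    rng = np.random.default_rng(seed)
    best = base or CalibrationFactors()
    best_metrics = evaluate_calibration(build_table(best), n_patients, seed,
                                        with_trial=with_trial)
    best_score = score(best_metrics)
    history = [(best, best_metrics, best_score)]
    if verbose:
        print(f"init score={best_score:.4f} {best_metrics}")
    for i in range(n_iter):
        cand = CalibrationFactors(
            p_auto_base=float(best.p_auto_base * np.exp(rng.normal(0, 0.3))),
            lesion_mult=float(np.clip(best.lesion_mult * np.exp(rng.normal(0, 0.2)),
                                      1.0, 6.0)),
            kill_mult_high=float(np.clip(best.kill_mult_high
                                         * np.exp(rng.normal(0, 0.1)), 1.0, 2.0)),
            age_gradient=float(np.clip(best.age_gradient + rng.normal(0, 0.03),
                                       0.0, 0.3)),
            treg_gradient=float(np.clip(best.treg_gradient + rng.normal(0, 0.02),
                                        -0.2, 0.2)),
            present_self_max=float(np.clip(best.present_self_max
                                           * np.exp(rng.normal(0, 0.25)),
                                           0.005, 0.3)),
        )
        metrics = evaluate_calibration(build_table(cand), n_patients,
                                       seed + 100 + i, with_trial=with_trial)
        sc = score(metrics)
        history.append((cand, metrics, sc))
        if verbose:
            print(f"[{i}] score={sc:.4f} {metrics}")
        if sc < best_score:
            best, best_metrics, best_score = cand, metrics, sc
    return best, best_metrics, history
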