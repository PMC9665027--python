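"""Configuration files, result directories and reproducibility manifests.

Trial configurations are single YAML documents (schema below); results
are written as tidy CSVs plus JSON summaries, together with a manifest
recording the config hash, package version, seed and per-stage patient
counts so any run can be reproduced byte-for-byte.

Config schema (top-level keys)::

    seed: int
    population:
      lesion_load:        {HIGH: p, LOW_MEDIUM: 1-p}
      oligoclonal_bands:  {PRESENT: q, ABSENT: 1-q}
      onset_age:          {18-29: a, 30-39: b, 40-49: c}
      disease_duration_years: float
      n_candidates: int
    inclusion:            # optional; omit for population-only runs
      min_relapses_lookback: int
      lookback_window_days: float
      exclusion_window_days: float
      require_symptomatic: bool
    arms:                 # optional; omit for population-only runs
      - {name, target_n, drug, dose_mg, interval_days, start_week, end_week}
    allocation_ratio: [ints]
    runin_years: float
    trial_weeks: int
    milestones: [weeks]
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
import time
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .pathology import RelapseEvent
from .treatments import TreatmentPlan
from .trial import (Arm, ConfigError, InclusionCriteria, PatientRecord,
                    PopulationResult, PopulationSpec, TrialConfig, TrialResult)

__all__ = [
    "load_population_config", "load_trial_config", "preset_path",
    "write_population_result", "write_trial_result", "write_manifest",
    "read_population_dir",
]

_IMMUNE_VARS = ("B", "TH", "IL2", "IFNG", "TGFB", "IgM", "IgG", "IgA")


def _version() -> str:
    from . import __version__
    return __version__


def preset_path(name: str) -> Path:
    """Path of a shipped preset config (population1, population2, affirm)."""
    ref = resources.files("rrmsim.presets").joinpath(f"{name}.yaml")
    with resources.as_file(ref) as p:
        return Path(p)


def _population_spec(doc: dict) -> PopulationSpec:
    try:
        pop = doc["population"]
    except KeyError as exc:
        raise ConfigError("config is missing the 'population' block") from exc
    for key in ("lesion_load", "oligoclonal_bands", "onset_age"):
        if key not in pop:
            raise ConfigError(f"population block is missing {key!r}")
    return PopulationSpec(
        lesion_load_dist={str(k): float(v) for k, v in pop["lesion_load"].items()},
        ocb_dist={str(k): float(v) for k, v in pop["oligoclonal_bands"].items()},
        onset_age_dist={str(k): float(v) for k, v in pop["onset_age"].items()},
        disease_duration_years=float(pop.get("disease_duration_years", 5.0)),
        n_candidates=int(pop.get("n_candidates", 100)),
    )


def load_population_config(path: str | Path) -> tuple[PopulationSpec, int]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _population_spec(doc), int(doc.get("seed", 0))


def load_trial_config(path: str | Path) -> TrialConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    spec = _population_spec(doc)
    inc = doc.get("inclusion", {})
    criteria = InclusionCriteria(
        min_relapses_lookback=int(inc.get("min_relapses_lookback", 1)),
        lookback_window_days=float(inc.get("lookback_window_days", 365)),
        exclusion_window_days=float(inc.get("exclusion_window_days", 30)),
        require_symptomatic=bool(inc.get("require_symptomatic", True)),
    )
    if "arms" not in doc or not doc["arms"]:
        raise ConfigError("trial config requires a non-empty 'arms' list")
    arms = []
    for a in doc["arms"]:
        plan = TreatmentPlan(
            drug=str(a.get("drug", "NONE")),
            dose_mg=float(a.get("dose_mg", 0.0)),
            interval_days=float(a.get("interval_days", 0.0)),
            start_week=float(a.get("start_week", 0.0)),
            end_week=float(a.get("end_week", doc.get("trial_weeks", 0))),
        )
        arms.append(Arm(name=str(a["name"]), plan=plan, target_n=int(a["target_n"])))
    return TrialConfig(
        population=spec,
        criteria=criteria,
        arms=arms,
        allocation_ratio=[int(r) for r in doc.get(
            "allocation_ratio", [a.target_n for a in arms])],
        trial_weeks=int(doc["trial_weeks"]),
        milestones=[float(w) for w in doc.get("milestones", [])],
        runin_years=doc.get("runin_years"),
        seed=int(doc.get("seed", 0)),
        expected_inclusion_rate=float(doc.get("expected_inclusion_rate", 0.25)),
    )


# ---------------------------------------------------------------------------
# writing results
# ---------------------------------------------------------------------------


def _write_patients_csv(path: Path, patients: list[PatientRecord]) -> None:
    cols = (["patient_id", "arm", "lesion_load", "ocb_status", "onset_age",
             "seed", "n_runin_relapses", "n_trial_relapses",
             "time_to_first_trial_relapse_weeks", "cumulative_oligo_loss"]
            + [f"mean_{v}" for v in _IMMUNE_VARS])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for i, p in enumerate(patients):
            w.writerow([i, p.arm or "", p.profile.lesion_load, p.profile.ocb_status,
                        p.profile.onset_age, p.profile.seed,
                        len(p.runin_relapses), len(p.trial_relapses),
                        "" if p.time_to_first_trial_relapse is None
                        else f"{p.time_to_first_trial_relapse:.6g}",
                        p.cumulative_loss]
                       + [f"{p.immune_means[v]:.10g}" for v in _IMMUNE_VARS])


def _write_relapses_csv(path: Path, patients: list[PatientRecord],
                        steps_per_day: int) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "phase", "start_day", "end_day", "magnitude"])
        for i, p in enumerate(patients):
            for ev in p.runin_relapses:
                w.writerow([i, "runin", ev.start_time // steps_per_day,
                            ev.end_time // steps_per_day, ev.magnitude])
            for ev in p.trial_relapses:
                w.writerow([i, "trial", ev.start_time // steps_per_day,
                            ev.end_time // steps_per_day, ev.magnitude])


def write_trajectory_csv(traj, path: str | Path, steps_per_day: int = 1) -> Path:
    """Export one patient's per-step trajectory as tidy CSV
    (columns: time, variable, value; time in days)."""
    from .engine import TRAJ_COLUMNS

    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "variable", "value"])
        for i, row in enumerate(np.asarray(traj)):
            t = i / steps_per_day
            for j, name in enumerate(TRAJ_COLUMNS):
                w.writerow([f"{t:g}", name, f"{row[j]:.10g}"])
    return path


def write_population_result(result: PopulationResult, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_patients_csv(outdir / "patients.csv", result.patients)
    _write_relapses_csv(outdir / "relapses.csv", result.patients,
                        result.steps_per_day)
    summary = {
        "version": 1,
        "kind": "population",
        "n_simulated": result.n_simulated,
        "n_with_relapse": sum(1 for p in result.patients if p.runin_relapses),
        "fraction_with_relapse": result.fraction_with_relapse,
        "runin_years": result.runin_years,
        "steps_per_day": result.steps_per_day,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return outdir


def write_trial_result(result: TrialResult, outdir: str | Path) -> Path:
    from .stats import arm_survival

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_patients_csv(outdir / "patients.csv", result.patients)
    _write_relapses_csv(outdir / "relapses.csv", result.patients,
                        result.steps_per_day)
    summary = {
        "version": 1,
        "kind": "trial",
        "trial_weeks": result.trial_weeks,
        "milestones": result.milestones,
        "n_sampled": result.n_sampled,
        "n_included": result.n_included,
        "seed": result.seed,
        "arms": result.arm_summaries,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    # per-arm administration log (one row per scheduled dose)
    with open(outdir / "administrations.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["arm", "drug", "dose_mg", "day"])
        for name, plan in (result.arm_plans or {}).items():
            from .treatments import schedule_doses
            for t in schedule_doses(plan, result.trial_weeks, result.steps_per_day):
                w.writerow([name, plan.drug, plan.dose_mg,
                            t // result.steps_per_day])
    for name in result.arm_names:
        curve = arm_survival(result, name)
        with open(outdir / f"km_{name}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["week", "at_risk", "events", "survival", "ci_low", "ci_high"])
            for i, t in enumerate(curve.event_times):
                w.writerow([f"{t:.6g}", int(curve.at_risk[i]), int(curve.events[i]),
                            f"{curve.estimate[i]:.10g}",
                            f"{curve.ci_low[i]:.10g}", f"{curve.ci_high[i]:.10g}"])
    return outdir


def write_manifest(outdir: str | Path, config_path: str | Path | None,
                   seed: int, stage_counts: dict, t_start: float) -> Path:
    """Atomically written reproducibility record of one CLI run."""
    outdir = Path(outdir)
    manifest = {
        "software": "rrmsim",
        "version": _version(),
        "config_sha256": (hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
                          if config_path else None),
        "seed": seed,
        "stage_counts": stage_counts,
        "wall_time_s": round(time.time() - t_start, 3),
        "finished_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    tmp = outdir / ".manifest.tmp"
    tmp.write_text(json.dumps(manifest, indent=2))
    final = outdir / "manifest.json"
    os.replace(tmp, final)
    return final


# ---------------------------------------------------------------------------
# reading results back (for the comparison command)
# ---------------------------------------------------------------------------


class _LoadedPatient:
    __slots__ = ("arm", "immune_means", "runin_relapses", "trial_relapses",
                 "time_to_first_trial_relapse", "cumulative_loss", "profile")

    def __init__(self):
        self.arm = None
        self.immune_means = {}
        self.runin_relapses = []
        self.trial_relapses = []
        self.time_to_first_trial_relapse = None
        self.cumulative_loss = 0
        self.profile = None


class _LoadedPopulation:
    def __init__(self, patients, summary):
        self.patients = patients
        self.summary = summary
        self.steps_per_day = summary.get("steps_per_day", 1)
        self.trial_weeks = summary.get("trial_weeks",
                                       summary.get("runin_years", 5.0) * 365.25 / 7)


def read_population_dir(path: str | Path) -> _LoadedPopulation:
    """Load a results directory (population or trial) for comparison."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"results directory not found: {path}")
    summary = json.loads((path / "summary.json").read_text())
    spd = summary.get("steps_per_day", 1)
    patients: dict[int, _LoadedPatient] = {}
    with open(path / "patients.csv") as fh:
        for row in csv.DictReader(fh):
            p = _LoadedPatient()
            p.arm = row["arm"] or None
            p.cumulative_loss = int(row["cumulative_oligo_loss"])
            for v in _IMMUNE_VARS:
                p.immune_means[v] = float(row[f"mean_{v}"])
            patients[int(row["patient_id"])] = p
    with open(path / "relapses.csv") as fh:
        for row in csv.DictReader(fh):
            ev = RelapseEvent(int(row["start_day"]) * spd,
                              int(row["end_day"]) * spd, int(row["magnitude"]))
            target = patients[int(row["patient_id"])]
            (target.runin_relapses if row["phase"] == "runin"
             else target.trial_relapses).append(ev)
    return _LoadedPopulation(list(patients.values()), summary)
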