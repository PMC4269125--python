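"""Readers and writers for the pipeline's plain-text artifacts.

Trial logs, ability tables and fitted-parameter tables are CSV; cohort
directories bundle them with a JSON config carrying the seed and config hash
so every artifact is traceable to its generator settings.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .abilities import ABILITY_COLUMNS
from .agent import PARAM_NAMES, TrialRecord
from .cohort import SyntheticCohort, SyntheticConfig
from .task import TaskConfig, walks_from_csv, walks_to_csv

__all__ = [
    "read_trials",
    "write_trials",
    "read_abilities",
    "write_abilities",
    "save_cohort",
    "load_cohort",
    "write_fits",
    "write_prior",
    "read_prior",
]

TRIAL_COLUMNS = ["subject_id", "trial", "a1", "s2", "common", "a2", "r"]


def write_trials(trials: dict[str, list[TrialRecord]], path) -> None:
    rows = []
    for sid in trials:
        for t in trials[sid]:
            rows.append((sid, t.trial, t.a1, t.s2, int(t.common), t.a2, t.r))
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials(path) -> dict[str, list[TrialRecord]]:
    """Read and validate a trial-log CSV into per-subject record lists.

    Actions, states and rewards must be 0/1; a malformed row raises with its
    line number (header = line 1).
    """
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in TRIAL_COLUMNS]
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if unknown or missing:
        raise ValueError(f"trial CSV schema mismatch: unknown={unknown} missing={missing}")
    if df.empty:
        raise ValueError(f"{path}: empty trial dataset")
    for col in ("a1", "s2", "common", "a2", "r"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(
                f"{path}: invalid value {df.loc[df.index[bad][0], col]!r} "
                f"in column {col!r} at line {line}"
            )
    out: dict[str, list[TrialRecord]] = {}
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial")
        out[str(sid)] = [
            TrialRecord(int(t), int(a1), int(s2), bool(c), int(a2), int(r))
            for t, a1, s2, c, a2, r in zip(
                sub["trial"], sub["a1"], sub["s2"], sub["common"], sub["a2"], sub["r"]
            )
        ]
    return out


def write_abilities(abilities: pd.DataFrame, path) -> None:
    abilities.to_csv(path, index=False, float_format="%.6f")


def read_abilities(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["subject_id", *ABILITY_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"abilities CSV missing columns: {missing}")
    return df


def save_cohort(cohort: SyntheticCohort, directory) -> Path:
    """Write a cohort directory: config.json, abilities.csv, true_params.csv,
    walks.csv, trials/<subject_id>.csv."""
    d = Path(directory)
    (d / "trials").mkdir(parents=True, exist_ok=True)
    cfg = asdict(cohort.config)
    cfg["task"] = asdict(cohort.config.task)
    cfg["config_hash"] = cohort.config.hash()
    (d / "config.json").write_text(json.dumps(cfg, indent=2, default=float))
    write_abilities(cohort.abilities, d / "abilities.csv")
    cohort.true_params.to_csv(d / "true_params.csv", index=False, float_format="%.8f")
    if cohort.config.shared_walks:
        walks_to_csv(cohort.walks["shared"], d / "walks.csv")
    else:
        for sid, w in cohort.walks.items():
            walks_to_csv(w, d / f"walks_{sid}.csv")
    for sid, recs in cohort.trials.items():
        write_trials({sid: recs}, d / "trials" / f"{sid}.csv")
    return d


def load_cohort(directory) -> SyntheticCohort:
    d = Path(directory)
    cfg = json.loads((d / "config.json").read_text())
    cfg.pop("config_hash", None)
    task = TaskConfig(**cfg.pop("task"))
    for key in ("pop_mu", "pop_sigma", "ability_means", "ability_sds"):
        cfg[key] = tuple(cfg[key])
    cfg["ability_ranges"] = tuple(tuple(r) for r in cfg["ability_ranges"])
    config = SyntheticConfig(task=task, **cfg)
    abilities = read_abilities(d / "abilities.csv")
    true_params = pd.read_csv(d / "true_params.csv")
    if config.shared_walks:
        walks = {"shared": walks_from_csv(d / "walks.csv")}
    else:
        walks = {
            sid: walks_from_csv(d / f"walks_{sid}.csv")
            for sid in abilities["subject_id"]
        }
    trials: dict[str, list[TrialRecord]] = {}
    for sid in abilities["subject_id"]:
        trials.update(read_trials(d / "trials" / f"{sid}.csv"))
    return SyntheticCohort(
        config=config,
        abilities=abilities,
        true_params=true_params,
        trials=trials,
        walks=walks,
        seed=config.seed,
    )


def write_fits(fits, subject_ids, path) -> None:
    """Fit table: model-scale parameters, unconstrained MAPs, NLL, flag."""
    from .agent import untransform_params

    rows = []
    for sid, f in zip(subject_ids, fits):
        model = untransform_params(f.map_estimate).to_array()
        rows.append(
            [sid, *model, *f.map_estimate, f.nll_at_map, int(f.converged)]
        )
    cols = (
        ["subject_id"]
        + list(PARAM_NAMES)
        + [f"{n}_unc" for n in PARAM_NAMES]
        + ["nll", "converged"]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.8f")


def write_prior(prior, path) -> None:
    Path(path).write_text(
        json.dumps({"mu": list(prior.mu), "sigma": list(prior.sigma)}, indent=2)
    )


def read_prior(path):
    from .hierarchy import PopulationPrior

    d = json.loads(Path(path).read_text())
    return PopulationPrior(np.asarray(d["mu"]), np.asarray(d["sigma"]))
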