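"""Trial-log CSV and configuration round-tripping.

The trial log is a plain CSV whose header matches the schema exactly (see
:data:`mbforage.task.LOG_COLUMNS`); configurations are YAML or JSON mappings
with three optional sections: ``task`` (block schedule), ``rule``
(plasticity variant and rates) and ``ensemble`` (KC representation
parameters).  Omitted fields take the documented defaults; unknown keys are
rejected rather than silently ignored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agent import KCEnsemble, PlasticityRule
from .task import LOG_COLUMNS, TaskConfig, Block

__all__ = [
    "TrialLogSchemaError",
    "read_trial_log",
    "write_trial_log",
    "load_config",
    "DEFAULT_TASK",
]

#: Default schedule: the three-block, 80-trial dynamic-foraging design.
DEFAULT_TASK = TaskConfig(
    blocks=(Block(80, (0.8, 0.2)), Block(80, (0.2, 0.8)), Block(80, (0.4, 0.1)))
)


class TrialLogSchemaError(ValueError):
    """A trial-log file violates the documented schema."""


def write_trial_log(log: pd.DataFrame, path) -> None:
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise TrialLogSchemaError(f"log is missing columns: {', '.join(missing)}")
    log[LOG_COLUMNS].to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    path = Path(path)
    log = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise TrialLogSchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    try:
        log = log.astype(
            {
                "fly_id": "int64",
                "trial_index": "int64",
                "block_index": "int64",
                "encounter_index": "int64",
                "odor_id": "int64",
                "accepted": "bool",
                "is_choice": "bool",
                "rewarded": "bool",
                "forced": "bool",
            }
        )
    except (ValueError, TypeError) as exc:
        raise TrialLogSchemaError(f"{path.name}: bad column types: {exc}") from exc
    _validate_log(log, path.name)
    return log[LOG_COLUMNS]


def _validate_log(log: pd.DataFrame, name: str) -> None:
    bad = log.index[log["rewarded"] & ~log["is_choice"]]
    if len(bad):
        raise TrialLogSchemaError(
            f"{name}: reward on non-choice row(s) at line(s) "
            f"{', '.join(str(i + 2) for i in bad[:5])}"  # +2: header + 1-based
        )
    for (fly, trial), g in log.groupby(["fly_id", "trial_index"]):
        if int(g["is_choice"].sum()) != 1:
            raise TrialLogSchemaError(
                f"{name}: fly {fly} trial {trial} has {int(g['is_choice'].sum())} choice rows"
            )
        enc = np.sort(g["encounter_index"].values)
        if not np.array_equal(enc, np.arange(1, len(g) + 1)):
            raise TrialLogSchemaError(
                f"{name}: fly {fly} trial {trial}: encounter_index not 1..n"
            )


_TASK_KEYS = {"blocks", "baiting", "n_odors", "seed"}
_RULE_KEYS = {"variant", "eta", "tau_r", "tau_s"}
_ENSEMBLE_KEYS = {"n_kc", "active_fraction", "overlap", "noise_sd", "n_odors"}


def load_config(path) -> dict:
    """Load a task/rule/ensemble config; returns the three built objects.

    Returns ``{"task": TaskConfig, "rule": PlasticityRule,
    "ensemble": KCEnsemble}`` with defaults for anything omitted.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path.name}: config must be a mapping")
    unknown = set(raw) - {"task", "rule", "ensemble"}
    if unknown:
        raise ValueError(f"{path.name}: unknown top-level key(s): {sorted(unknown)}")

    task_raw = dict(raw.get("task") or {})
    if set(task_raw) - _TASK_KEYS:
        raise ValueError(f"{path.name}: unknown task key(s): {sorted(set(task_raw) - _TASK_KEYS)}")
    if "blocks" in task_raw:
        task = TaskConfig.from_dict(
            {**DEFAULT_TASK.to_dict(), **task_raw}
        )
    else:
        base = DEFAULT_TASK.to_dict()
        base.update(task_raw)
        task = TaskConfig.from_dict(base)

    rule_raw = dict(raw.get("rule") or {})
    if set(rule_raw) - _RULE_KEYS:
        raise ValueError(f"{path.name}: unknown rule key(s): {sorted(set(rule_raw) - _RULE_KEYS)}")
    rule = PlasticityRule(**rule_raw)

    ens_raw = dict(raw.get("ensemble") or {})
    if set(ens_raw) - _ENSEMBLE_KEYS:
        raise ValueError(
            f"{path.name}: unknown ensemble key(s): {sorted(set(ens_raw) - _ENSEMBLE_KEYS)}"
        )
    ensemble = KCEnsemble(**ens_raw)
    return {"task": task, "rule": rule, "ensemble": ensemble}
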