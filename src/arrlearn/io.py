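"""Trial-table file dialect and run configuration.

The single interchange format is a comma-separated, UTF-8, header-row table
with one row per trial (long format).  Columns are the trial-record fields::

    subject_id, experiment_id, block_index, condition, global_trial, task,
    trial_within_task, pair_id, chosen_option, correct, feedback_points,
    missed[, response_side]

``response_side`` ('left'/'right'/'none') is optional on read but required by
the button-run exclusion rule.  Missed trials carry ``chosen_option='none'``,
an empty ``correct`` field and the timeout penalty as ``feedback_points``.
Training-block rows use ``block_index=0`` and ``global_trial`` -23..0 so the
experiment proper keeps numbering 1..360; rows sort by (subject, global_trial).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDataset
from .models import TRIAL_COLUMNS
from .task import CONDITIONS, TASKS

_REQUIRED = [c for c in TRIAL_COLUMNS if c != "response_side"]


class SchemaError(ValueError):
    """A trial table violates the file dialect."""


def _check(condition: np.ndarray, message: str) -> None:
    bad = np.flatnonzero(~np.asarray(condition))
    if bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-basing
        raise SchemaError(f"{message} (file rows {rows}"
                          + (", ..." if bad.size > 5 else "") + ")")


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Type and range-check a trial table; returns it with normalized dtypes."""
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    for col in ("experiment_id", "block_index", "global_trial", "trial_within_task",
                "missed"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    df["feedback_points"] = pd.to_numeric(df["feedback_points"], errors="raise")
    df["correct"] = pd.to_numeric(df["correct"], errors="coerce").astype("Int64")
    _check(df["experiment_id"].isin([1, 2, 3]), "experiment_id must be 1, 2 or 3")
    _check(df["task"].isin(TASKS), "task must be inducer or reference")
    _check(df["condition"].isin(CONDITIONS), "condition must be low/medium/high")
    _check(df["trial_within_task"].between(1, 12), "trial_within_task must be in 1..12")
    _check(df["block_index"].between(0, 15), "block_index must be in 0..15")
    _check(df["missed"].isin([0, 1]), "missed must be 0 or 1")
    _check(df["chosen_option"].isin(["better", "worse", "none"]),
           "chosen_option must be better/worse/none")
    _check((df["missed"] == 1) == (df["chosen_option"] == "none"),
           "missed=1 exactly when chosen_option is none")
    ok = df["missed"] == 1
    _check(ok | df["correct"].notna().to_numpy(), "correct required on non-missed trials")
    _check(ok | df["correct"].isin([0, 1]).to_numpy(), "correct must be 0 or 1")
    return df


def read_trial_table(path) -> CohortDataset:
    """Read and validate a trial-table file into a cohort."""
    df = pd.read_csv(path)
    df = validate_trial_table(df)
    df = df.sort_values(["subject_id", "global_trial"]).reset_index(drop=True)
    subjects = (df[["subject_id", "experiment_id"]].drop_duplicates()
                .set_index("subject_id"))
    return CohortDataset(trials=df, subjects=subjects)


def write_trial_table(cohort, path) -> Path:
    """Write a cohort (or bare trial DataFrame) deterministically: fixed column
    order, rows sorted by (subject, global_trial), UTF-8, header row."""
    trials = cohort.trials if hasattr(cohort, "trials") else cohort
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    out = (trials[cols].sort_values(["subject_id", "global_trial"])
           .reset_index(drop=True))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, encoding="utf-8")
    return path


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a key-value mapping")
    return cfg


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping (stamped into artifacts)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
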