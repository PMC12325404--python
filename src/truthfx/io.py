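"""Data interchange: trial-table CSV schema, config files, result JSON.

Trial tables are long-format CSVs with the columns ``participant_id``,
``statement_id``, ``repeated`` (0/1), and ``judgment`` (0/1); each
(participant, statement) pair may appear at most once.  Configuration is
read from JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "validate_trials", "read_config", "write_json"]


class TrialSchemaError(ValueError):
    pass


def validate_trials(trials: pd.DataFrame, source: str = "trial table") -> pd.DataFrame:
    """Validate the trial-table schema; errors name the offending row."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialSchemaError(f"{source}: missing column(s) {missing}")
    trials = trials[list(TRIAL_COLUMNS)].copy()
    for col in ("repeated", "judgment"):
        values = trials[col]
        bad = ~values.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TrialSchemaError(
                f"{source}: non-binary value {values.iloc[row]!r} in column {col!r} at row {row}"
            )
        trials[col] = values.astype(np.int8)
    dup = trials.duplicated(subset=["participant_id", "statement_id"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        pair = trials.iloc[row][["participant_id", "statement_id"]].tolist()
        raise TrialSchemaError(f"{source}: duplicate (participant, statement) pair {pair} at row {row}")
    return trials


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    path = Path(path)
    return validate_trials(pd.read_csv(path), source=str(path))


def write_trials(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_trials(trials, source="in-memory table").to_csv(path, index=False)
    return path


def read_config(path) -> dict:
    """Read a JSON or YAML configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        return yaml.safe_load(text)
    return json.loads(text)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(payload: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")
    return path
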