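"""ChoiceDataset: the long trial table shared by every pipeline stage.

Columns (fixed CSV header): subject, group, block, trial, choice, outcome,
correct, stage.  ``group`` is one of {"AUDP", "HC"}; ``outcome`` is coded
win = +1 / loss = -1; ``correct`` flags whether the chosen stimulus was the
stage's designated correct stimulus (regardless of the feedback received).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "GROUPS", "validate_dataset", "read_dataset", "write_dataset", "dataset_hash"]

COLUMNS = ["subject", "group", "block", "trial", "choice", "outcome", "correct", "stage"]
GROUPS = ("AUDP", "HC")

_DTYPES = {
    "subject": str,
    "group": str,
    "block": np.int64,
    "trial": np.int64,
    "choice": np.int64,
    "outcome": np.int64,
    "correct": bool,
    "stage": np.int64,
}


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Check ChoiceDataset invariants; returns the frame (possibly re-typed)."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = df.copy()
    for col, dt in _DTYPES.items():
        df[col] = df[col].astype(dt)
    if not df["outcome"].isin([-1, 1]).all():
        raise ValueError("outcome must be -1/+1")
    if not df["choice"].isin([0, 1]).all():
        raise ValueError("choice must be 0/1")
    bad_group = set(df["group"].unique()) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown groups: {sorted(bad_group)}")
    for (subj, block), g in df.groupby(["subject", "block"], sort=False):
        t = g["trial"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"subject {subj} block {block} has fewer than 2 trials")
        if np.any(np.diff(t) != 1):
            raise ValueError(f"subject {subj} block {block}: trials not consecutive")
    return df


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a ChoiceDataset CSV (empty fields are treated as missing)."""
    df = pd.read_csv(path, dtype={"subject": str})
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    validate_dataset(df[COLUMNS])
    df[COLUMNS].to_csv(path, index=False)


def dataset_hash(df: pd.DataFrame) -> str:
    """Stable content hash used to guard model comparisons on matched data."""
    canon = df[COLUMNS].sort_values(["subject", "block", "trial"]).reset_index(drop=True)
    return hashlib.md5(canon.to_csv(index=False).encode()).hexdigest()
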