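"""Delimited-text I/O for feature tables and questionnaire tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .features import FEATURE_COLUMNS
from .study import SRS_SUBSCALES, ValidationError

SRS_COLUMNS = ["Person", "Group", "Time", *SRS_SUBSCALES, "Total"]
MODEL_FRAME_COLUMNS = ["Person", "Session", "Condition", "Task"]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table {path} is missing columns {missing}")
    bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()
                   & df["value"].notna()]
    if len(bad):
        raise ValidationError(
            f"feature table {path}: non-numeric 'value' in row(s) {list(bad[:5])}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def write_srs_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_srs_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SRS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"SRS table {path} is missing columns {missing}")
    for col in SRS_COLUMNS[2:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"SRS table {path}: non-numeric {col!r} in row(s) {list(bad[:5])}")
        df[col] = vals
    return df


def write_model_frame(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_model_frame(path: str | Path, outcome: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MODEL_FRAME_COLUMNS + [outcome] if c not in df.columns]
    if missing:
        raise ValidationError(f"model frame {path} is missing columns {missing}")
    return df
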