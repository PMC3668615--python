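"""Readers and writers for the study's delimited-table formats.

All tables are UTF-8 CSV with a header, comma delimiter and quoted text
fields (free text may contain commas and newlines).  Reading validates the
schema and referential integrity and raises named errors; unknown extra
columns are accepted with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .textprep import RawResponse

__all__ = [
    "ValidationError",
    "read_responses",
    "read_participants",
    "write_responses",
    "responses_from_frame",
]

RESPONSE_COLUMNS = (
    "response_id",
    "participant_id",
    "clip_id",
    "dataset",
    "prompt_a",
    "prompt_b",
)
PARTICIPANT_COLUMNS = ("participant_id", "dataset", "age", "gender", "education")


class ValidationError(ValueError):
    """An input table violates the schema or its integrity invariants."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what} table has extra columns (kept): {extra}", stacklevel=3)


def read_responses(
    path: str | Path, participants: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read and validate a responses table.

    Checks: required columns present; response_id unique; (participant_id,
    clip_id) unique within each dataset (no participant sees a clip twice);
    and, when a participants table is supplied, that every response's
    participant exists in it.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"responses file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, RESPONSE_COLUMNS, "responses")

    dup_ids = df[df.duplicated("response_id", keep=False)]
    if not dup_ids.empty:
        rows = (dup_ids.index + 2).tolist()  # +2: header + 1-based
        raise ValidationError(f"duplicate response_id values at file rows {rows}")
    dup_pc = df[df.duplicated(["dataset", "participant_id", "clip_id"], keep=False)]
    if not dup_pc.empty:
        rows = (dup_pc.index + 2).tolist()
        raise ValidationError(
            f"duplicate (participant_id, clip_id) pairs within a dataset at "
            f"file rows {rows}"
        )
    if participants is not None:
        known = set(participants["participant_id"].astype(str))
        orphans = sorted(set(df["participant_id"]) - known)
        if orphans:
            raise ValidationError(
                f"responses reference unknown participant ids: {orphans[:10]}"
            )
    return df


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read and validate a participants table (demographics)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"participants file not found: {path}")
    df = pd.read_csv(path, keep_default_na=False)
    _check_columns(df, PARTICIPANT_COLUMNS, "participants")
    df["participant_id"] = df["participant_id"].astype(str)
    dup = df[df.duplicated("participant_id", keep=False)]
    if not dup.empty:
        rows = (dup.index + 2).tolist()
        raise ValidationError(f"duplicate participant_id values at file rows {rows}")
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    df["education"] = pd.to_numeric(df["education"], errors="raise")
    return df


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def responses_from_frame(df: pd.DataFrame) -> list[RawResponse]:
    """Convert a validated responses frame into RawResponse records."""
    return [
        RawResponse(
            response_id=str(r.response_id),
            participant_id=str(r.participant_id),
            clip_id=str(r.clip_id),
            dataset_label=str(r.dataset),
            prompt_a_text=str(r.prompt_a),
            prompt_b_text=str(r.prompt_b),
        )
        for r in df.itertuples(index=False)
    ]
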