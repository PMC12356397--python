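"""Canonical trial-log CSV format.

Header (exact, in order): participant_id, block, trial_index, sigma,
letter_shown, category_shown, response_letter, response_category,
correct_category, increment.  UTF-8; booleans written as 0/1; sigma and
increment at full precision.  Validation is row-level and names the
offending row and column.
"""

from __future__ import annotations

import pandas as pd

from .sdt import TrialRecord
from .stimuli import LETTERS, LETTER_CATEGORY

TRIAL_LOG_COLUMNS = ["participant_id", "block", "trial_index", "sigma",
                     "letter_shown", "category_shown", "response_letter",
                     "response_category", "correct_category", "increment"]

_BLOCK_LABELS = {"practice", "quest", "block2", "block3", "block4", "block5"}


def records_to_frame(records) -> pd.DataFrame:
    rows = [{
        "participant_id": r.participant_id, "block": r.block,
        "trial_index": r.trial_index, "sigma": r.sigma,
        "letter_shown": r.letter_shown, "category_shown": r.category_shown,
        "response_letter": r.response_letter,
        "response_category": r.response_category,
        "correct_category": int(r.correct_category), "increment": r.increment,
    } for r in records]
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for i, row in df.iterrows():
        records.append(TrialRecord(
            participant_id=str(row["participant_id"]), block=str(row["block"]),
            trial_index=int(row["trial_index"]), sigma=float(row["sigma"]),
            letter_shown=str(row["letter_shown"]),
            response_letter=str(row["response_letter"]),
            increment=float(row["increment"]),
            category_shown=str(row["category_shown"]),
            response_category=str(row["response_category"])))
    return records


def write_trial_log(records_or_frame, path) -> None:
    df = (records_or_frame if isinstance(records_or_frame, pd.DataFrame)
          else records_to_frame(records_or_frame))
    df.to_csv(path, index=False)


class TrialLogError(ValueError):
    """Schema violation in a trial-log file, naming the row and column."""


def _fail(row, column, message):
    raise TrialLogError(f"row {row}, column {column!r}: {message}")


def read_trial_log(path, as_records: bool = False):
    """Read and validate a trial-log CSV; empty logs return an empty frame."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed / truncated file
        raise TrialLogError(f"could not parse {path}: {exc}") from exc
    if list(df.columns) != TRIAL_LOG_COLUMNS:
        raise TrialLogError(
            f"bad header: expected {TRIAL_LOG_COLUMNS}, got {list(df.columns)}")
    if df.empty:
        import warnings
        warnings.warn(f"{path}: trial log contains a header only")
        out = df.assign(trial_index=pd.Series(dtype=int),
                        sigma=pd.Series(dtype=float),
                        correct_category=pd.Series(dtype=int),
                        increment=pd.Series(dtype=float))
        return [] if as_records else out[TRIAL_LOG_COLUMNS]

    for col in ("trial_index", "correct_category"):
        try:
            df[col] = df[col].astype(int)
        except ValueError:
            bad = df.index[~df[col].str.fullmatch(r"-?\d+")][0]
            _fail(bad, col, f"not an integer: {df.at[bad, col]!r}")
    for col in ("sigma", "increment"):
        try:
            df[col] = df[col].astype(float)
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            _fail(bad, col, f"not a number: {df.at[bad, col]!r}")

    for i, row in df.iterrows():
        if row["block"] not in _BLOCK_LABELS:
            _fail(i, "block", f"unknown block {row['block']!r}")
        for col in ("letter_shown", "response_letter"):
            if row[col] not in LETTERS:
                _fail(i, col, f"letter {row[col]!r} outside the stimulus set")
        if row["category_shown"] != LETTER_CATEGORY[row["letter_shown"]]:
            _fail(i, "category_shown", "inconsistent with letter_shown")
        if row["response_category"] != LETTER_CATEGORY[row["response_letter"]]:
            _fail(i, "response_category", "inconsistent with response_letter")
        expected = int(row["category_shown"] == row["response_category"])
        if row["correct_category"] != expected:
            _fail(i, "correct_category", "inconsistent with categories")
        if row["correct_category"] not in (0, 1):
            _fail(i, "correct_category", "must be 0 or 1")
    return frame_to_records(df) if as_records else df
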