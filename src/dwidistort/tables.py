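"""Delimited-text tables: rater ordinal scores and the per-patient cohort table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

SCORE_COLUMNS = ["subject", "rater", "item", "score"]

#: Columns of the per-patient cohort table consumed by the statistics layer.
COHORT_COLUMNS = [
    "patient_id",
    "air_supine_cm3",
    "air_prone_cm3",
    "distortion_supine_mm",
    "distortion_prone_mm",
    "likert_supine",
    "likert_prone",
]


def read_score_table(path, scale: tuple[int, int] = (1, 5)) -> pd.DataFrame:
    """Read a subject/rater/item/score table and validate the ordinal scale.

    Parameters
    ----------
    scale : (low, high)
        Inclusive bounds of the declared ordinal scale; any score outside the
        scale raises :class:`ValidationError`.
    """
    df = pd.read_csv(path)
    extra = set(df.columns) - set(SCORE_COLUMNS)
    if extra:
        raise SchemaError(f"unknown score columns {sorted(extra)}")
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing score columns {sorted(missing)}")
    scores = df["score"].to_numpy()
    if not np.all(np.isfinite(scores)) or not np.allclose(scores, np.rint(scores)):
        raise ValidationError("scores must be integers")
    lo, hi = scale
    bad = (scores < lo) | (scores > hi)
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} scores outside the declared scale [{lo}, {hi}]")
    df["score"] = scores.astype(int)
    return df


def read_cohort_table(path) -> pd.DataFrame:
    """Read the per-patient paired cohort table; unknown columns are rejected."""
    df = pd.read_csv(path)
    extra = set(df.columns) - set(COHORT_COLUMNS)
    if extra:
        raise SchemaError(f"unknown cohort columns {sorted(extra)}")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing cohort columns {sorted(missing)}")
    for col in COHORT_COLUMNS[1:5]:
        if (df[col] < 0).any():
            raise ValidationError(f"{col} contains negative values")
    for col in ("likert_supine", "likert_prone"):
        if not df[col].isin(range(1, 6)).all():
            raise ValidationError(f"{col} outside the 1-5 Likert scale")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df[COHORT_COLUMNS].to_csv(path, index=False)


__all__ = ["SCORE_COLUMNS", "COHORT_COLUMNS", "read_score_table",
           "read_cohort_table", "write_cohort_table"]
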