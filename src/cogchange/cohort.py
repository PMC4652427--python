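"""Two-visit cohort table: validation, CSV I/O, change scores, case matching.

The canonical on-disk format is a wide CSV with one row per subject
(``subject_id, group, age, education_years, gender, AQ_y1, AQ_y2, ...``);
empty cells denote missing scores.  In memory the cohort is a thin wrapper
around a :class:`pandas.DataFrame` in that same layout, so all downstream
analyses can work with ordinary pandas idioms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .instruments import (
    CSV_COLUMNS,
    GROUPS,
    INSTRUMENTS,
    STAGING_SCALES,
    measure_range_width,
    valid_score,
)

__all__ = [
    "Cohort",
    "CohortValidationError",
    "MatchedCohort",
    "read_cohort",
    "write_cohort",
    "compute_change_scores",
    "match_cases",
]

_GENDERS = ("M", "F")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema; carries row diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "cohort validation failed:\n" + "\n".join(f"  - {p}" for p in problems)
        )


def _validate_frame(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    missing_cols = [c for c in ("subject_id", "group", "age", "education_years", "gender") if c not in df.columns]
    if missing_cols:
        return [f"missing required column(s): {', '.join(missing_cols)}"]

    dup = df["subject_id"][df["subject_id"].duplicated()]
    for sid in dup.unique():
        problems.append(f"duplicate subject_id {sid!r}")

    for idx, row in df.iterrows():
        sid = row["subject_id"]
        if row["group"] not in GROUPS:
            problems.append(f"row {idx} ({sid}): unknown group {row['group']!r}")
        if row["gender"] not in _GENDERS:
            problems.append(f"row {idx} ({sid}): unknown gender {row['gender']!r}")
        if not (40 <= row["age"] <= 110):
            problems.append(f"row {idx} ({sid}): age {row['age']} outside [40, 110]")
        if row["education_years"] < 0:
            problems.append(f"row {idx} ({sid}): negative education")
        for name in (*INSTRUMENTS, *STAGING_SCALES):
            for visit in (1, 2):
                col = f"{name}_y{visit}"
                if col not in df.columns:
                    continue
                val = row[col]
                if pd.isna(val):
                    continue
                if not valid_score(name, float(val)):
                    problems.append(
                        f"row {idx} ({sid}): {col}={val} out of range for {name}"
                    )
    return problems


@dataclass
class Cohort:
    """A validated two-visit cohort.

    Parameters
    ----------
    df
        Wide table in the canonical column layout; score columns may be
        missing entirely (treated as all-missing) or contain NaN cells.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in CSV_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col in ("subject_id", "group", "gender") else np.nan
        numeric = [c for c in CSV_COLUMNS if c not in ("subject_id", "group", "gender")]
        df[numeric] = df[numeric].apply(pd.to_numeric, errors="coerce")
        df = df[list(CSV_COLUMNS)].reset_index(drop=True)
        problems = _validate_frame(df)
        if problems:
            raise CohortValidationError(problems)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def _trusted(cls, df: pd.DataFrame) -> "Cohort":
        # internal: wrap an already-validated (or deliberately unvalidated,
        # e.g. latent-score) frame without re-running range checks
        cohort = cls.__new__(cls)
        cohort.df = df.reset_index(drop=True)
        return cohort

    @property
    def groups(self) -> list[str]:
        present = set(self.df["group"])
        return [g for g in GROUPS if g in present]

    def subset(self, group: str) -> "Cohort":
        return Cohort._trusted(self.df[self.df["group"] == group])

    def scores(self, measure: str, visit: int) -> pd.Series:
        return self.df.set_index("subject_id")[f"{measure}_y{visit}"]

    def paired_scores(self, measure: str) -> pd.DataFrame:
        """Complete-case (year1, year2) pairs for one measure, indexed by subject."""
        wide = self.df.set_index("subject_id")[[f"{measure}_y1", f"{measure}_y2"]]
        wide = wide.dropna()
        wide.columns = ["year1", "year2"]
        return wide


@dataclass
class MatchedCohort:
    """Case-control pairs plus the cases left unmatched."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file in the canonical layout (or any layout mappable onto it).
    schema
        Optional mapping from canonical column name to the header actually
        present in the file, for ingesting externally produced tables.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return Cohort(df)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical layout (empty cell = missing)."""
    cohort.df.to_csv(path, index=False)


def compute_change_scores(cohort: Cohort) -> pd.DataFrame:
    """Per-subject change scores, defined as ``year2 - year1`` for every measure.

    With this sign convention a positive change means worsening on AQ, FAQ
    and the staging scales, and a negative change means worsening on the
    MMSE.  Subjects missing either visit are omitted for that measure
    (complete-case per instrument pair); the returned frame has one column
    per measure, indexed by ``subject_id``, with NaN where undefined.
    """
    out = {}
    idx = cohort.df.set_index("subject_id")
    for name in (*INSTRUMENTS, *STAGING_SCALES):
        change = idx[f"{name}_y2"] - idx[f"{name}_y1"]
        width = measure_range_width(name)
        bad = change.abs() > width
        if bad.any():  # cannot happen on a validated cohort; guard for direct use
            raise ValueError(f"{name} change exceeds instrument range width")
        out[name] = change
    return pd.DataFrame(out)


def match_cases(
    cohort: Cohort,
    age_tol: float = 2.0,
    edu_tol: float = 2.0,
) -> MatchedCohort:
    """Greedy without-replacement matching of impaired cases to CN controls.

    Each aMCI/AD case is matched to a cognitively normal control of the same
    gender with age and education within ``age_tol`` / ``edu_tol`` years.
    Cases are processed in sorted ``subject_id`` order; among eligible
    controls the nearest by absolute age difference is taken, ties broken by
    absolute education difference, then by control ``subject_id`` — the
    procedure is deterministic for a given table.  Controls are consumed
    without replacement; cases with no eligible control are reported in
    ``unmatched``.
    """
    df = cohort.df
    controls = df[df["group"] == "CN"][["subject_id", "age", "education_years", "gender"]]
    cases = df[df["group"].isin(("aMCI", "AD"))][
        ["subject_id", "age", "education_years", "gender"]
    ].sort_values("subject_id")

    available = {
        row.subject_id: row for row in controls.itertuples(index=False)
    }
    result = MatchedCohort()
    for case in cases.itertuples(index=False):
        candidates = [
            c
            for c in available.values()
            if c.gender == case.gender
            and abs(c.age - case.age) <= age_tol
            and abs(c.education_years - case.education_years) <= edu_tol
        ]
        if not candidates:
            result.unmatched.append(case.subject_id)
            continue
        best = min(
            candidates,
            key=lambda c: (
                abs(c.age - case.age),
                abs(c.education_years - case.education_years),
                c.subject_id,
            ),
        )
        del available[best.subject_id]
        result.pairs.append((case.subject_id, best.subject_id))
    return result
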