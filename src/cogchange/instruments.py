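"""Instrument and staging-scale registry.

Three score instruments are tracked across two annual visits:

* AQ  — 21-item informant-based dementia screen, total 0-27, higher = worse.
* FAQ — informant-rated instrumental activities of daily living, 0-30,
  higher = worse.
* MMSE — 30-point objective cognitive screen, lower = worse.

Three ordinal staging scales record global disease severity:

* FAST, GDS — 7-category dementia staging, higher = more severe.
* CDR-GS — Clinical Dementia Rating global score in {0, 0.5, 1, 2, 3}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "Instrument",
    "StagingScale",
    "INSTRUMENTS",
    "STAGING_SCALES",
    "GROUPS",
    "SCORE_COLUMNS",
    "CSV_COLUMNS",
]


@dataclass(frozen=True)
class Instrument:
    """A continuous (integer-valued) score instrument measured at both visits."""

    name: str
    lo: float
    hi: float
    higher_is_worse: bool

    def in_range(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class StagingScale:
    """An ordinal global-severity scale; categories are listed worst-last."""

    name: str
    categories: tuple[float, ...]

    def valid(self, value: float) -> bool:
        return value in self.categories

    def rank(self, value: float) -> int:
        return self.categories.index(value)

    def next_up(self, value: float) -> float:
        """The next-more-severe category (saturates at the top)."""
        i = self.rank(value)
        return self.categories[min(i + 1, len(self.categories) - 1)]


INSTRUMENTS: dict[str, Instrument] = {
    "AQ": Instrument("AQ", 0, 27, higher_is_worse=True),
    "FAQ": Instrument("FAQ", 0, 30, higher_is_worse=True),
    "MMSE": Instrument("MMSE", 0, 30, higher_is_worse=False),
}

STAGING_SCALES: dict[str, StagingScale] = {
    "FAST": StagingScale("FAST", tuple(float(c) for c in range(1, 8))),
    "GDS": StagingScale("GDS", tuple(float(c) for c in range(1, 8))),
    "CDR": StagingScale("CDR", (0.0, 0.5, 1.0, 2.0, 3.0)),
}

#: Diagnostic groups, in reporting order.
GROUPS: tuple[str, ...] = ("CN", "aMCI", "AD")

#: Two-visit score columns in the canonical wide CSV layout.
SCORE_COLUMNS: tuple[str, ...] = tuple(
    f"{name}_y{v}" for name in (*INSTRUMENTS, *STAGING_SCALES) for v in (1, 2)
)

#: Full canonical CSV header.
CSV_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "age",
    "education_years",
    "gender",
    *SCORE_COLUMNS,
)


def measure_range_width(name: str) -> float:
    inst = INSTRUMENTS.get(name)
    if inst is not None:
        return inst.hi - inst.lo
    scale = STAGING_SCALES[name]
    return scale.categories[-1] - scale.categories[0]


def valid_score(name: str, value: float) -> bool:
    """Whether ``value`` is admissible for instrument or staging scale ``name``."""
    if name in INSTRUMENTS:
        return INSTRUMENTS[name].in_range(value)
    return STAGING_SCALES[name].valid(value)


def all_measures() -> Sequence[str]:
    return (*INSTRUMENTS, *STAGING_SCALES)
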