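"""Published summary statistics of the validation cohort.

The package was validated against a two-annual-visit brain- and
body-donation cohort of 202 older adults (101 cognitively normal, 62
amnestic MCI, 39 AD) assessed with the AQ, FAQ and MMSE.  Only
group-level summary statistics of that cohort are public; they are
embedded here so that

* the effect-size, confidence-interval and sample-size machinery can be
  exercised directly on the published numbers ("summary mode"), and
* the synthetic-cohort generator can be calibrated to produce data with
  the same first- and second-moment structure.

FAQ effect-size cells in the published summary are internally
inconsistent (the printed pooled SD does not reproduce the printed ES),
so FAQ rows carry an ``es_consistent=False`` flag and are excluded from
exact cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SummaryRow",
    "REFERENCE_ROWS",
    "REFERENCE_DEMOGRAPHICS",
    "REFERENCE_GENDER_COUNTS",
    "TRIAL_YEARS",
    "reference_row",
]


@dataclass(frozen=True)
class SummaryRow:
    """One published (group, instrument) summary line.

    ``mean_change`` and ``sd_change`` are year2−year1 score points;
    ``pooled_sd`` pools the two visit SDs; ``es``, ``reliability`` and
    ``d`` are the printed (display-rounded) derived quantities;
    ``n_per_arm`` is the printed per-arm trial sample size.
    """

    group: str
    instrument: str
    n: int
    mean_change: float
    sd_change: float
    ci95: tuple[float, float]
    pooled_sd: float
    es: float
    reliability: float
    d: float
    n_per_arm: int
    es_consistent: bool = True


REFERENCE_ROWS: tuple[SummaryRow, ...] = (
    SummaryRow("aMCI", "AQ", 62, 1.66, 4.96, (0.40, 2.92), 6.10, 0.27, 0.65, 0.33, 251),
    SummaryRow("aMCI", "FAQ", 62, 2.05, 5.79, (0.54, 3.56), 3.29, 0.30, 0.63, 0.35, 224, es_consistent=False),
    SummaryRow("aMCI", "MMSE", 62, -0.55, 2.54, (-1.19, 0.10), 2.47, 0.22, 0.56, 0.24, 597),
    SummaryRow("AD", "AQ", 39, 2.49, 4.77, (0.94, 4.03), 6.75, 0.37, 0.64, 0.43, 232),
    SummaryRow("AD", "FAQ", 39, 3.59, 4.91, (2.00, 5.18), 5.36, 0.52, 0.81, 0.84, 119, es_consistent=False),
    SummaryRow("AD", "MMSE", 39, -2.13, 3.35, (-3.23, -1.03), 6.34, 0.34, 0.79, 0.52, 157),
    SummaryRow("CN", "AQ", 101, 0.47, 2.73, (-0.07, 1.00), 3.37, 0.14, 0.69, 0.18, 340),
    SummaryRow("CN", "FAQ", 101, 0.33, 1.80, (-0.03, 0.69), 3.29, 0.11, 0.73, 0.15, 300, es_consistent=False),
    SummaryRow("CN", "MMSE", 101, 0.05, 1.71, (-0.29, 0.39), 2.47, 0.02, 0.41, 0.02, 660),
)

#: Per-group demographics of the validation cohort:
#: (n, age mean, age SD, education mean, education SD, n male, n female).
REFERENCE_DEMOGRAPHICS: dict[str, tuple[int, float, float, float, float, int, int]] = {
    "CN": (101, 81.76, 7.23, 14.69, 2.50, 53, 48),
    "aMCI": (62, 81.57, 7.59, 15.18, 2.56, 33, 29),
    "AD": (39, 81.82, 6.92, 14.15, 2.55, 21, 18),
}

#: Gender counts (male, female) per group, for the 2×3 chi-square check.
REFERENCE_GENDER_COUNTS: dict[str, tuple[int, int]] = {
    "CN": (53, 48),
    "aMCI": (33, 29),
    "AD": (21, 18),
}

#: Hypothetical trial length (years) per diagnostic group, matching the
#: published sample-size projections: faster-progressing groups get
#: shorter trials.
TRIAL_YEARS: dict[str, int] = {"AD": 2, "aMCI": 3, "CN": 5}


def reference_row(group: str, instrument: str) -> SummaryRow:
    for row in REFERENCE_ROWS:
        if row.group == group and row.instrument == instrument:
            return row
    raise KeyError(f"no reference row for ({group}, {instrument})")
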