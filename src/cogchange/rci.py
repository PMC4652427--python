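"""Reliable change indices for two-visit instrument scores.

The reliable change index (RCI) asks whether an individual's observed
change exceeds what measurement error alone would produce.  Parameters
are estimated from the cognitively normal reference group:

    SEm    = SD_ref · sqrt(1 − r)       (standard error of measurement)
    SEdiff = sqrt(2) · SEm              (standard error of a difference)
    RCI_i  = (change_i − practice) / SEdiff

where ``r`` is the CN Spearman test–retest reliability, ``SD_ref`` the CN
Year-1 SD (the classic Jacobson–Truax reference), and ``practice`` the CN
mean retest change (nonzero only in the practice-corrected variant, used
for performance-based tests where retest exposure inflates scores).
|RCI| ≥ 1.645 — the two-sided 90% band, boundary included — is read as
clinically significant change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, compute_change_scores
from .instruments import INSTRUMENTS
from .sensitivity import reliability

__all__ = [
    "RCIParams",
    "DEFAULT_VARIANTS",
    "rci_parameters",
    "rci_scores",
    "pct_outside",
    "rci_table",
]

#: Which RCI variant each instrument gets by default: informant-based
#: instruments use the classic reliability-corrected form; the MMSE, an
#: objective performance test, additionally corrects for practice effects.
DEFAULT_VARIANTS: dict[str, str] = {
    "AQ": "classic",
    "FAQ": "classic",
    "MMSE": "practice_corrected",
}


@dataclass(frozen=True)
class RCIParams:
    instrument: str
    variant: str
    reliability_r: float
    sd_ref: float
    sem: float
    sediff: float
    ci90_halfwidth: float
    practice_effect: float
    critical_value: float = 1.645


def rci_parameters(
    cn_scores1: Sequence[float],
    cn_scores2: Sequence[float],
    variant: str = "classic",
    instrument: str = "",
    critical_value: float = 1.645,
) -> RCIParams:
    """Estimate RCI parameters from cognitively normal reference pairs.

    ``variant`` is ``"classic"`` (practice effect fixed at 0) or
    ``"practice_corrected"`` (practice effect = CN mean year2−year1).
    """
    if variant not in ("classic", "practice_corrected"):
        raise ValueError(f"unknown RCI variant {variant!r}")
    y1 = np.asarray(cn_scores1, dtype=float)
    y2 = np.asarray(cn_scores2, dtype=float)
    if y1.size != y2.size or y1.size < 3:
        raise ValueError("need at least three reference pairs")
    sd_ref = float(y1.std(ddof=1))
    if sd_ref == 0:
        raise ValueError("degenerate reference data: zero Year-1 variance")
    r = reliability(y1, y2)
    sem = sd_ref * math.sqrt(max(1 - r, 0.0))
    sediff = math.sqrt(2) * sem
    practice = float((y2 - y1).mean()) if variant == "practice_corrected" else 0.0
    return RCIParams(
        instrument=instrument,
        variant=variant,
        reliability_r=r,
        sd_ref=sd_ref,
        sem=sem,
        sediff=sediff,
        ci90_halfwidth=critical_value * sediff,
        practice_effect=practice,
        critical_value=critical_value,
    )


def rci_scores(changes: Sequence[float], params: RCIParams) -> np.ndarray:
    """Standardize change scores: (change − practice effect) / SEdiff."""
    if params.sediff == 0:
        raise ValueError("SEdiff is zero (perfect reliability): RCI undefined")
    x = np.asarray(changes, dtype=float)
    return (x - params.practice_effect) / params.sediff


def pct_outside(changes: Sequence[float], params: RCIParams) -> float:
    """Percent of subjects with |RCI| at or beyond the critical value."""
    x = np.asarray(changes, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no change scores to classify")
    z = np.abs(rci_scores(x, params))
    return 100.0 * float(np.mean(z >= params.critical_value))


def rci_table(
    cohort: Cohort,
    variants: dict[str, str] | None = None,
    critical_value: float = 1.645,
) -> pd.DataFrame:
    """RCI parameters (from the CN group) and percent-outside per group.

    One row per instrument with the CN-estimated reliability, SEm, SEdiff
    and 90% band, plus the percentage of aMCI and AD subjects (and CN,
    for reference) whose change falls outside the band.
    """
    variants = {**DEFAULT_VARIANTS, **(variants or {})}
    cn = cohort.subset("CN")
    changes = compute_change_scores(cohort)
    group_of = cohort.df.set_index("subject_id")["group"]
    rows = []
    for instrument in INSTRUMENTS:
        ref = cn.paired_scores(instrument)
        params = rci_parameters(
            ref["year1"], ref["year2"], variants[instrument], instrument, critical_value
        )
        row: dict[str, object] = {
            "instrument": instrument,
            "variant": params.variant,
            "reliability": params.reliability_r,
            "sd_ref": params.sd_ref,
            "sem": params.sem,
            "sediff": params.sediff,
            "ci90_halfwidth": params.ci90_halfwidth,
            "practice_effect": params.practice_effect,
        }
        for group in cohort.groups:
            grp_changes = changes.loc[group_of == group, instrument].dropna()
            row[f"pct_outside_{group}"] = (
                pct_outside(grp_changes, params) if len(grp_changes) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
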