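"""Sensitivity-to-change effect sizes for two-visit repeated measures.

For each (diagnostic group, instrument) cell the chain is:

* mean change score (year2 − year1) with a t-based 95% CI;
* pooled SD across the two visits, ``sqrt((sd1^2 + sd2^2)/2)``;
* uncorrected effect size ``ES = |mean change| / pooled SD`` (the pooled
  SD is the appropriate denominator in a correlated design);
* test–retest reliability ``r`` = Spearman correlation of the two visits;
* reliability-corrected effect size ``d = ES / sqrt(2(1 − r))``, with the
  usual Cohen-style interpretation bands.

Full precision is carried through the whole chain; rounding happens only
at display.  Computing d from a display-rounded ES gives visibly
different second decimals, so the unrounded convention is the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .instruments import INSTRUMENTS

__all__ = [
    "SensitivityResult",
    "mean_change_ci",
    "pooled_sd",
    "effect_size",
    "reliability",
    "corrected_d",
    "interpret_d",
    "sensitivity_table",
    "sensitivity_from_summary",
]

#: Interpretation bands for the corrected effect size d. Each boundary is
#: assigned to the higher band (0.20 -> small, 0.50 -> moderate, 0.80 -> large).
_BANDS = ((0.80, "large"), (0.50, "moderate"), (0.20, "small"), (0.0, "trivial"))


@dataclass(frozen=True)
class SensitivityResult:
    """One row of the sensitivity-to-change table."""

    group: str
    instrument: str
    n: int
    mean_change: float
    sd_change: float
    ci95: tuple[float, float]
    pooled_sd: float
    es: float
    reliability_r: float
    d: float
    band: str


def mean_change_ci(
    changes: Sequence[float], level: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Mean, sample SD and two-sided t interval of a sequence of change scores."""
    x = np.asarray(changes, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two change scores")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    tcrit = stats.t.ppf(1 - (1 - level) / 2, n - 1)
    half = tcrit * sd / math.sqrt(n)
    return mean, sd, (mean - half, mean + half)


def pooled_sd(sd1: float, sd2: float) -> float:
    """Pooled SD across two visits: sqrt((sd1^2 + sd2^2) / 2)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    return math.sqrt((sd1**2 + sd2**2) / 2)


def effect_size(mean_change: float, pooled: float) -> float:
    """Uncorrected effect size |mean change| / pooled SD (reported absolute)."""
    if pooled <= 0:
        raise ValueError("pooled SD must be positive")
    return abs(mean_change) / pooled


def reliability(scores1: Sequence[float], scores2: Sequence[float]) -> float:
    """Test–retest reliability: Spearman correlation of the two visits."""
    x = np.asarray(scores1, dtype=float)
    y = np.asarray(scores2, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired scores")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant scores")
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) > 1 - 1e-12:  # perfectly monotone data: remove float fuzz
        rho = math.copysign(1.0, rho)
    return rho


def corrected_d(es: float, r: float) -> float:
    """Reliability-corrected effect size d = ES / sqrt(2(1 − r))."""
    if r >= 1:
        raise ValueError("reliability must be < 1")
    return es / math.sqrt(2 * (1 - r))


def interpret_d(d: float) -> str:
    """Cohen-style band for d: trivial < 0.20 ≤ small < 0.50 ≤ moderate < 0.80 ≤ large."""
    if d < 0:
        raise ValueError("d must be non-negative")
    for lo, name in _BANDS:
        if d >= lo:
            return name
    return "trivial"


def _cell(group: str, instrument: str, pairs: pd.DataFrame) -> SensitivityResult:
    y1 = pairs["year1"].to_numpy(float)
    y2 = pairs["year2"].to_numpy(float)
    mean, sd, ci = mean_change_ci(y2 - y1)
    pooled = pooled_sd(float(np.std(y1, ddof=1)), float(np.std(y2, ddof=1)))
    es = effect_size(mean, pooled)
    r = reliability(y1, y2)
    d = corrected_d(es, r)
    return SensitivityResult(
        group, instrument, len(pairs), mean, sd, ci, pooled, es, r, d, interpret_d(d)
    )


def sensitivity_table(cohort: Cohort) -> pd.DataFrame:
    """Sensitivity-to-change results for every (group, instrument) cell.

    Returns one row per diagnostic group and instrument, chaining mean
    change, CI, pooled SD, ES, Spearman reliability and corrected d at
    full precision.  Groups or cells without at least two complete score
    pairs are omitted.
    """
    rows = []
    for group in cohort.groups:
        sub = cohort.subset(group)
        for instrument in INSTRUMENTS:
            pairs = sub.paired_scores(instrument)
            if len(pairs) < 3:
                continue
            res = _cell(group, instrument, pairs)
            rows.append(res.__dict__ | {"ci95_low": res.ci95[0], "ci95_high": res.ci95[1]})
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.drop(columns="ci95")
    return table


def sensitivity_from_summary(
    mean_change: float, pooled: float, r: float
) -> tuple[float, float, str]:
    """ES, d and band from published summary inputs (no subject-level data)."""
    es = effect_size(mean_change, pooled)
    d = corrected_d(es, r)
    return es, d, interpret_d(d)
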