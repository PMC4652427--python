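"""Descriptive statistics: demographics tests, Spearman correlation tables.

Everything here is deliberately non-parametric.  Two-visit cognitive
scores are discretized, bounded and typically skewed, so normality
(checked with Shapiro–Wilk, reported for information) routinely fails;
group comparisons therefore use Kruskal–Wallis for continuous
demographics and chi-square for gender composition, and all
correlations are Spearman.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, compute_change_scores
from .instruments import INSTRUMENTS, STAGING_SCALES

__all__ = [
    "TestResult",
    "spearman",
    "correlation_tables",
    "change_correlations",
    "group_tests",
    "gender_chi_square",
    "shapiro_wilk",
    "demographics_table",
]


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float
    df: float | None = None


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Average-rank Spearman rho with its t-approximation p-value.

    The p-value uses t = rho·sqrt((n−2)/(1−rho²)) on n−2 degrees of
    freedom, appropriate at the sample sizes this package targets.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * float(stats.t.sf(abs(t), n - 2))
    return rho, p


def correlation_tables(cohort: Cohort) -> dict[int, pd.DataFrame]:
    """Per-visit instrument × staging Spearman correlation matrices.

    Returns ``{1: frame, 2: frame}`` with AQ/FAQ/MMSE rows and
    FAST/GDS/CDR columns; each cell is computed on the complete pairs
    for that visit across the whole cohort.
    """
    out: dict[int, pd.DataFrame] = {}
    df = cohort.df
    for visit in (1, 2):
        mat = pd.DataFrame(index=list(INSTRUMENTS), columns=list(STAGING_SCALES), dtype=float)
        for inst in INSTRUMENTS:
            for scale in STAGING_SCALES:
                sub = df[[f"{inst}_y{visit}", f"{scale}_y{visit}"]].dropna()
                rho, _ = spearman(sub.iloc[:, 0], sub.iloc[:, 1])
                mat.loc[inst, scale] = rho
        out[visit] = mat
    return out


def change_correlations(cohort: Cohort) -> pd.DataFrame:
    """Spearman correlations between instrument change scores (AQ vs FAQ/MMSE)."""
    changes = compute_change_scores(cohort)
    rows = []
    for a, b in (("AQ", "FAQ"), ("AQ", "MMSE")):
        sub = changes[[a, b]].dropna()
        rho, p = spearman(sub[a], sub[b])
        rows.append({"pair": f"{a}-{b}", "rho": rho, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


def group_tests(cohort: Cohort) -> dict[str, TestResult]:
    """Demographic homogeneity checks across diagnostic groups.

    Kruskal–Wallis (tie-corrected) for age and education; chi-square
    without continuity correction for the gender × group table.
    """
    groups = cohort.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out: dict[str, TestResult] = {}
    for var in ("age", "education_years"):
        samples = [cohort.df.loc[cohort.df["group"] == g, var].to_numpy() for g in groups]
        h, p = stats.kruskal(*samples)
        out[var] = TestResult("kruskal-wallis", float(h), float(p), df=len(groups) - 1)
    counts = [
        [int(((cohort.df["group"] == g) & (cohort.df["gender"] == sex)).sum()) for g in groups]
        for sex in ("M", "F")
    ]
    out["gender"] = gender_chi_square(counts)
    return out


def gender_chi_square(counts: Sequence[Sequence[int]]) -> TestResult:
    """Chi-square test on a gender × group count table (no Yates correction)."""
    table = np.asarray(counts, dtype=float)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult("chi-square", float(chi2), float(p), df=float(df))


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro–Wilk normality test (informational; the pipeline is non-parametric)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = stats.shapiro(x)
    return TestResult("shapiro-wilk", float(w), float(p))


def demographics_table(cohort: Cohort) -> pd.DataFrame:
    """Group-wise demographic summary (mean ± SD age/education, gender counts)."""
    rows = []
    for g in cohort.groups + ["all"]:
        sub = cohort.df if g == "all" else cohort.df[cohort.df["group"] == g]
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "age_mean": sub["age"].mean(),
                "age_sd": sub["age"].std(ddof=1),
                "education_mean": sub["education_years"].mean(),
                "education_sd": sub["education_years"].std(ddof=1),
                "n_male": int((sub["gender"] == "M").sum()),
                "n_female": int((sub["gender"] == "F").sum()),
            }
        )
    table = pd.DataFrame(rows)
    tests = group_tests(cohort)
    table.attrs["tests"] = {k: (v.statistic, v.p) for k, v in tests.items()}
    return table
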