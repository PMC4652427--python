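"""Prediction of global-stage worsening from instrument change scores.

Subjects are dichotomized on whether each staging scale (FAST, GDS,
CDR global score) increased between the two visits — any move to a more
severe category counts, improvement does not.  Univariate logistic
regressions then relate each instrument's change score to each increase
outcome; odds ratios are per 1-point change-score increase, with Wald
95% intervals and two-sided Wald p-values.  Multiplicity is controlled
either by a fixed per-comparison threshold (default 0.006, i.e. a
0.05-family level spread over the nine tests per group) or by
Benjamini–Hochberg step-up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort, compute_change_scores
from .instruments import INSTRUMENTS, STAGING_SCALES

__all__ = [
    "LogisticFit",
    "MultiplicityRule",
    "SeparationError",
    "dichotomize_increase",
    "fit_univariate_logistic",
    "apply_multiplicity",
    "global_change_table",
]


class SeparationError(RuntimeError):
    """The change score perfectly separates the outcome: ML estimate diverges."""


@dataclass(frozen=True)
class MultiplicityRule:
    """How p-values across a block of tests are converted to significance flags."""

    mode: str = "fixed_threshold"   # or "benjamini_hochberg"
    level: float = 0.006

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_threshold", "benjamini_hochberg"):
            raise ValueError(f"unknown multiplicity mode {self.mode!r}")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")


@dataclass(frozen=True)
class LogisticFit:
    predictor: str
    outcome: str
    beta: float
    se_beta: float
    or_: float
    ci95: tuple[float, float]
    p: float
    n: int
    converged: bool


def dichotomize_increase(stage_y1: float, stage_y2: float, scale: str) -> int:
    """1 if the staging value moved to a more severe category, else 0."""
    sc = STAGING_SCALES[scale]
    if not (sc.valid(float(stage_y1)) and sc.valid(float(stage_y2))):
        raise ValueError(f"invalid {scale} category: {stage_y1!r} or {stage_y2!r}")
    return int(sc.rank(float(stage_y2)) > sc.rank(float(stage_y1)))


def _check_separation(x: np.ndarray, y: np.ndarray) -> None:
    # complete separation for a univariate predictor with intercept:
    # all cases lie strictly to one side of all controls
    x1, x0 = x[y == 1], x[y == 0]
    if x1.min() > x0.max() or x1.max() < x0.min():
        raise SeparationError("change score completely separates the outcome")


def fit_univariate_logistic(
    x: Sequence[float],
    y: Sequence[int],
    predictor: str = "x",
    outcome: str = "y",
) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome on one change score.

    Returns the slope on the log-odds scale, its Wald SE, the odds ratio
    per 1-point increase with its Wald 95% CI, and the two-sided Wald
    p-value.  Raises on single-class outcomes and on complete separation
    rather than returning a divergent estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.size != y.size or x.size < 10:
        raise ValueError("need at least 10 paired observations")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome contains a single class")
    _check_separation(x, y)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=False, maxiter=200, gtol=1e-8, method="bfgs")
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se > 1e3:
        raise SeparationError("quasi-separation: Wald SE diverges")
    z = 1.959963984540054  # Phi^{-1}(0.975)
    p = max(2 * _ndtr(-abs(beta / se)), 1e-300)  # clamp: keep p in (0, 1]
    return LogisticFit(
        predictor=predictor,
        outcome=outcome,
        beta=beta,
        se_beta=se,
        or_=math.exp(beta),
        ci95=(math.exp(beta - z * se), math.exp(beta + z * se)),
        p=p,
        n=int(x.size),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def _ndtr(v: float) -> float:
    from scipy.special import ndtr

    return float(ndtr(v))


def apply_multiplicity(pvals: Sequence[float], rule: MultiplicityRule) -> np.ndarray:
    """Significance flags for a block of p-values under the given rule."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if rule.mode == "fixed_threshold":
        return p <= rule.level
    # Benjamini-Hochberg step-up
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    thresh = rule.level * (np.arange(1, m + 1) / m)
    below = ranked <= thresh
    flags = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        flags[order[: k + 1]] = True
    return flags


def global_change_table(
    cohort: Cohort, rule: MultiplicityRule = MultiplicityRule()
) -> pd.DataFrame:
    """Logistic fits of every stage-increase outcome on every change score.

    One block per diagnostic group plus a pooled all-groups block, each
    with 3 predictors × 3 outcomes; the multiplicity rule is applied
    within each block.  Cells whose outcome is single-class or separated
    are reported with NaN estimates and a note.
    """
    changes = compute_change_scores(cohort)
    df = cohort.df.set_index("subject_id")
    blocks = [(g, df[df["group"] == g]) for g in cohort.groups] + [("all", df)]
    rows: list[dict[str, object]] = []
    for label, block in blocks:
        block_rows = []
        for predictor in INSTRUMENTS:
            for outcome in STAGING_SCALES:
                sub = block[[f"{outcome}_y1", f"{outcome}_y2"]].join(
                    changes[predictor].rename("change")
                ).dropna()
                base = {"group": label, "predictor": predictor, "outcome": outcome}
                try:
                    y = [
                        dichotomize_increase(a, b, outcome)
                        for a, b in zip(sub[f"{outcome}_y1"], sub[f"{outcome}_y2"])
                    ]
                    fit = fit_univariate_logistic(
                        sub["change"], y, predictor, outcome
                    )
                    block_rows.append(
                        base
                        | {
                            "or": fit.or_,
                            "ci95_low": fit.ci95[0],
                            "ci95_high": fit.ci95[1],
                            "p": fit.p,
                            "n": fit.n,
                            "note": "",
                        }
                    )
                except (ValueError, SeparationError) as exc:
                    block_rows.append(
                        base
                        | {
                            "or": np.nan,
                            "ci95_low": np.nan,
                            "ci95_high": np.nan,
                            "p": np.nan,
                            "n": len(sub),
                            "note": str(exc),
                        }
                    )
        pvals = [r["p"] for r in block_rows if np.isfinite(r["p"])]
        flags = apply_multiplicity(pvals, rule) if pvals else np.zeros(0, bool)
        it = iter(flags)
        for r in block_rows:
            r["significant"] = bool(next(it)) if np.isfinite(r["p"]) else False
        rows.extend(block_rows)
    return pd.DataFrame(rows)
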