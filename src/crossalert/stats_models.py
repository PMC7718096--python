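"""Bivariate tests and logistic covariate models for crossover/outcome analysis.

Chi-square (Pearson, no continuity correction by default) and Welch t tests
for bivariate comparisons; maximum-likelihood logistic regression with Wald
95% confidence intervals for the covariate analysis, with all categorical
covariates coded as dichotomous indicators (January, benefit types, ages
19/26/65, therapeutic classes, sex).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwo:
    """Exposed/unexposed x event/non-event counts.

    a = exposed events, b = exposed non-events,
    c = unexposed events, d = unexposed non-events.
    """

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table total must be positive")
        if min(self.a + self.b, self.c + self.d) == 0 or min(
            self.a + self.c, self.b + self.d
        ) == 0:
            raise ValueError("zero margin: chi-square undefined")

    @property
    def odds_ratio(self) -> float:
        return (self.a * self.d) / (self.b * self.c)


@dataclass
class RegressionSpec:
    outcome: str
    covariates: Sequence[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.covariates:
            raise ValueError("at least one covariate is required")


class SeparationError(RuntimeError):
    """Perfect separation or non-convergence in the logistic fit."""


def chi_square_test(table: TwoByTwo, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and two-sided p for a 2x2 table."""
    table.validate()
    obs = np.array([[table.a, table.b], [table.c, table.d]])
    res = stats.chi2_contingency(obs, correction=correction)
    return float(res.statistic), float(res.pvalue)


def welch_t_test(
    group_a, group_b, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided t test, unequal variances (Welch) by default."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            logger.warning("both groups constant and equal; p = 1 by convention")
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def fit_logistic(
    spec: RegressionSpec, data: pd.DataFrame, maxiter: int = 200
) -> pd.DataFrame:
    """ML logistic fit; per-covariate odds ratios with Wald 95% CIs.

    Returns a frame with columns term, odds_ratio, ci_low, ci_high, p.
    Convergence is by statsmodels' Newton criterion (gradient tolerance
    1e-8); non-convergence or perfect separation raises SeparationError
    rather than returning a silently unstable fit.
    """
    spec.validate()
    y = data[spec.outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome must have both classes present")
    X = sm.add_constant(data[list(spec.covariates)].astype(float))
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
    except Exception as exc:  # PerfectSeparationError and friends
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge")
    ci = fit.conf_int(alpha=0.05)
    rows = []
    for term in spec.covariates:
        rows.append(
            {
                "term": term,
                "odds_ratio": float(np.exp(fit.params[term])),
                "ci_low": float(np.exp(ci.loc[term, 0])),
                "ci_high": float(np.exp(ci.loc[term, 1])),
                "p": float(fit.pvalues[term]),
            }
        )
    return pd.DataFrame(rows)


def format_p(p: float, floor: float = 0.001) -> str:
    """p-value string with the conventional '<.001' floor."""
    if p < floor:
        return "<.001"
    return f"{p:.3f}".lstrip("0") if p < 1 else "1.000"
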