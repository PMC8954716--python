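"""Association statistics for exposure-outcome analyses on 2x2 tables.

Implements the group-comparison toolkit used throughout the pipeline: 2x2
contingency construction (severe-MVM exposure x high-risk screen), the
cross-product odds ratio with the Woolf (logit-scale) 95% confidence
interval, the Pearson chi-square test without continuity correction,
two-group continuous comparisons with a normality-gated choice between
Student's t and Mann-Whitney U, and a two-proportion sample-size formula.

Notation for the 2x2 table::

                 outcome+   outcome-
    exposed         a          b
    unexposed       c          d

OR = (a*d)/(b*c); the 95% CI is exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d)).
The chi-square statistic uses the closed form n*(ad-bc)^2 / (r1*r2*c1*c2)
with 1 degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "ComparisonResult",
    "build_2x2",
    "odds_ratio",
    "pearson_chi2",
    "associate",
    "compare_continuous",
    "power_two_proportions",
]

Z_95 = stats.norm.ppf(0.975)  # 1.959964...


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-outcome counts."""

    a: int  # exposed, outcome
    b: int  # exposed, no outcome
    c: int  # unexposed, outcome
    d: int  # unexposed, no outcome

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    chi2_statistic: Optional[float]
    p_value: Optional[float]
    or_defined: bool = True
    chi2_defined: bool = True
    zero_cell_adjusted: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    method_used: str  # "t" | "mann_whitney"
    statistic: float


def build_2x2(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
) -> ContingencyTable:
    """Cross-classify two boolean cohort columns into a 2x2 table.

    Rows are exposure (True first), columns outcome (True first). Missing
    values are an error listing the offending participants.
    """
    for col in (exposure, outcome):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort")
    sub = cohort[[exposure, outcome]]
    bad = sub.isna().any(axis=1)
    if bad.any():
        if "participant_id" in cohort.columns:
            ids = list(cohort.loc[bad, "participant_id"].astype(str))
        else:
            ids = list(cohort.index[bad])
        raise ValueError(f"missing exposure/outcome values for participants: {ids}")
    e = sub[exposure].astype(bool).to_numpy()
    o = sub[outcome].astype(bool).to_numpy()
    return ContingencyTable(
        a=int((e & o).sum()),
        b=int((e & ~o).sum()),
        c=int((~e & o).sum()),
        d=int((~e & ~o).sum()),
    )


def odds_ratio(
    table: ContingencyTable,
    zero_cell: str = "undefined",
    conf_level: float = 0.95,
) -> AssociationResult:
    """Cross-product odds ratio with the Woolf logit-scale confidence interval.

    Parameters
    ----------
    table
        The 2x2 counts.
    zero_cell
        Policy when any cell is zero: ``"undefined"`` (default — OR and CI
        reported as None with ``or_defined=False``) or ``"haldane"``
        (Haldane-Anscombe +0.5 added to every cell, flagged in the result).
    """
    if zero_cell not in ("undefined", "haldane"):
        raise ValueError(f"unknown zero-cell policy {zero_cell!r}")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    adjusted = False
    if min(a, b, c, d) == 0:
        if zero_cell == "undefined":
            return AssociationResult(None, None, None, None, None, or_defined=False)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        adjusted = True
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + conf_level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return AssociationResult(
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - z * se),
        ci_high=math.exp(math.log(or_) + z * se),
        chi2_statistic=None,
        p_value=None,
        zero_cell_adjusted=adjusted,
    )


def pearson_chi2(
    table: ContingencyTable,
    correction: bool = False,
) -> tuple[Optional[float], Optional[float]]:
    """Pearson chi-square statistic and p-value (df=1) for a 2x2 table.

    No continuity correction by default (set ``correction=True`` for the
    Yates-corrected sensitivity analysis). Degenerate margins (an empty row
    or column) leave the statistic undefined: returns (None, None).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if n == 0 or 0 in (r1, r2, c1, c2):
        return (None, None)
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2, 0.0)
    statistic = n * diff**2 / (r1 * r2 * c1 * c2)
    return (float(statistic), float(stats.chi2.sf(statistic, df=1)))


def associate(
    table: ContingencyTable,
    zero_cell: str = "undefined",
    correction: bool = False,
) -> AssociationResult:
    """OR with CI plus Pearson chi-square for one table, in one result."""
    base = odds_ratio(table, zero_cell=zero_cell)
    statistic, p = pearson_chi2(table, correction=correction)
    return AssociationResult(
        odds_ratio=base.odds_ratio,
        ci_low=base.ci_low,
        ci_high=base.ci_high,
        chi2_statistic=statistic,
        p_value=p,
        or_defined=base.or_defined,
        chi2_defined=statistic is not None,
        zero_cell_adjusted=base.zero_cell_adjusted,
    )


def _normalish(x: np.ndarray, alpha: float = 0.05) -> bool:
    # Shapiro-Wilk needs n>=3 and non-constant data
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def compare_continuous(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
) -> ComparisonResult:
    """Two-group comparison of a continuous variable.

    ``method="auto"`` uses Student's t when both samples pass a Shapiro-Wilk
    normality check at alpha=0.05, otherwise Mann-Whitney U; tiny groups
    (n<3) or zero-variance t-test degeneracies fall back to Mann-Whitney.
    Explicit ``method="t"`` or ``method="mann_whitney"`` overrides the gate.
    """
    if method not in ("auto", "t", "mann_whitney"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        method = "t" if (_normalish(x) and _normalish(y)) else "mann_whitney"
    if method == "t":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # zero pooled variance: t undefined; identical constants are a
            # non-difference, distinct constants a certain one
            method = "mann_whitney"
        else:
            res = stats.ttest_ind(x, y)
            return ComparisonResult(float(res.pvalue), "t", float(res.statistic))
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return ComparisonResult(float(res.pvalue), "mann_whitney", float(res.statistic))


def power_two_proportions(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
) -> int:
    """Per-group sample size to detect p1 vs p2 (two-sided normal approximation).

    Uses the standard pooled-variance formula

        n = [ z_{1-a/2} sqrt(2 pbar qbar) + z_{power} sqrt(p1 q1 + p2 q2) ]^2
            / (p1 - p2)^2,   pbar = (p1+p2)/2,

    rounded up to the next integer.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must be in (0, 1), got {p}")
    if p1 == p2:
        raise ValueError("p1 == p2: no detectable difference (infinite n)")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    pbar = (p1 + p2) / 2
    num = (za * math.sqrt(2 * pbar * (1 - pbar)) + zb * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    return math.ceil(num / (p1 - p2) ** 2)
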