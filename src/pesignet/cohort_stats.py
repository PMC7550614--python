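"""Baseline-table statistics from printed summary data.

2x2 contingency tests with Yates continuity correction (with Fisher's exact
as the sparse-table fallback) and two-sample pooled-variance t-tests computed
directly from group means, SDs and sizes — the tests that reproduce a
clinical baseline table when only summary rows are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


class TestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float

    def to_json_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p": self.pvalue}


@dataclass(frozen=True)
class TwoByTwo:
    """Cell counts with rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in cells):
            raise ValueError(f"cell counts must be non-negative integers: {cells}")
        if sum(cells) < 1:
            raise ValueError("table total must be >= 1")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class GroupSummary:
    """Two-group summary: (mean, sd, n) per group."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("sd must be >= 0")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")


def chi2_yates(t: TwoByTwo) -> TestResult:
    """Pearson chi-square with Yates continuity correction, df = 1.

    Statistic: sum over cells of max(|O - E| - 0.5, 0)^2 / E.  Requires all
    margins non-zero; sparse tables should use ``fisher_exact`` instead.
    """
    m = t.matrix
    if np.any(m.sum(axis=0) == 0) or np.any(m.sum(axis=1) == 0):
        raise ValueError("zero margin: use fisher_exact for this table")
    stat, p, df, _ = stats.chi2_contingency(m, correction=True)
    return TestResult(float(stat), float(df), float(p))


def fisher_exact(t: TwoByTwo) -> TestResult:
    """Two-sided Fisher exact test: sum of hypergeometric probabilities of
    tables at most as likely as the observed one, margins fixed."""
    res = stats.fisher_exact(t.matrix, alternative="two-sided")
    return TestResult(float(res.statistic), 0.0, float(res.pvalue))


def pooled_t_from_summary(g: GroupSummary, welch: bool = False) -> TestResult:
    """Two-sided Student's t from summary statistics.

    Pooled (equal-variance) by default, df = n1 + n2 - 2; set ``welch`` for
    the unequal-variance form.  Degenerate zero-variance inputs short-circuit
    to p = 1 (equal means) or p = 0 with a warning (differing means).
    """
    if g.n1 + g.n2 < 3:
        raise ValueError("need n1 + n2 >= 3")
    if g.sd1 == 0 and g.sd2 == 0:
        if g.mean1 == g.mean2:
            return TestResult(0.0, float(g.n1 + g.n2 - 2), 1.0)
        log.warning("both SDs are zero with differing means; p = 0")
        return TestResult(np.inf, float(g.n1 + g.n2 - 2), 0.0)
    res = stats.ttest_ind_from_stats(
        g.mean1, g.sd1, g.n1, g.mean2, g.sd2, g.n2, equal_var=not welch
    )
    if welch:
        v1, v2 = g.sd1**2 / g.n1, g.sd2**2 / g.n2
        df = (v1 + v2) ** 2 / (v1**2 / (g.n1 - 1) + v2**2 / (g.n2 - 1))
    else:
        df = g.n1 + g.n2 - 2
    return TestResult(float(res.statistic), float(df), float(res.pvalue))
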