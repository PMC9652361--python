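"""The two tests applied to phenotype class tables, computed from formulas.

* Two-sided chi-square on a 2×2 contingency table,
  χ² = n (ad − bc)² / ((a+b)(c+d)(a+c)(b+d)), df = 1, with the Yates
  continuity correction available but off by default.
* One-sample two-sided t test of a set of values against a fixed H0 mean
  (the expected mean of the control population),
  t = (x̄ − µ0) / (s / √n), df = n − 1.

p-values come from the reference chi-square / t distributions (scipy).
Raw p-values are reported; optional Bonferroni/Holm adjustment is applied to
a family the caller assembles, since the tables themselves do not define one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import StatisticsError

__all__ = ["TestResult", "chi2_2x2", "one_sample_t", "collapse_to_2x2", "adjust_pvalues"]


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    test: str


def chi2_2x2(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test on a 2×2 table [[a, b], [c, d]]."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatisticsError(f"need a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise StatisticsError("counts must be non-negative integers")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins) or n == 0:
        raise StatisticsError("chi-square undefined: a marginal total is zero")
    expected = np.outer([a + b, c + d], [a + c, b + d]) / n
    if expected.min() < 5:
        warnings.warn(
            f"smallest expected count is {expected.min():.2f} (< 5); "
            "the chi-square approximation may be poor", stacklevel=2)
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / math.prod(margins)
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=float(stat), df=1, p_value=p,
                      test="chi2_2x2_yates" if yates else "chi2_2x2")


def one_sample_t(values, mu0: float) -> TestResult:
    """Two-sided one-sample t test of `values` against the H0 mean `mu0`."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatisticsError("one-sample t needs at least 2 values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise StatisticsError("one-sample t undefined: zero sample variance")
    n = x.size
    t = (float(np.mean(x)) - float(mu0)) / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return TestResult(statistic=t, df=n - 1, p_value=min(p, 1.0), test="one_sample_t")


def collapse_to_2x2(counts, row_a: str, row_b: str, positive_classes) -> np.ndarray:
    """Collapse a condition × class count table to a 2×2 for two conditions.

    Columns listed in ``positive_classes`` are pooled (e.g. class II+III+IV)
    against the remaining classes, mirroring the pairwise "vs." comparisons
    applied to phenotype incidence tables.
    """
    positive = [c for c in positive_classes]
    rows = []
    for cond in (row_a, row_b):
        row = counts.loc[cond]
        pos = int(row[positive].sum())
        neg = int(row.sum() - pos)
        rows.append([pos, neg])
    return np.asarray(rows, dtype=int)


def adjust_pvalues(p_values, method: str = "holm") -> list[float]:
    """Bonferroni or Holm adjustment over a caller-supplied test family."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if method == "bonferroni":
        return list(np.minimum(p * m, 1.0))
    if method != "holm":
        raise StatisticsError(f"unknown adjustment {method!r}")
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return list(adj)
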