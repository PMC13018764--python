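"""Paired and group statistics: McNemar's chi-square on discordant
categories, Benjamini-Hochberg FDR, Welch one-way ANOVA and pairwise Welch
t-tests with Holm adjustment.

Adjustment families are never pooled across analysis blocks: one family per
(score type x grouping block), mirroring how the comparisons are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateGroupError, UndefinedTestError
from .scores import DOCTOR_MORE, PARENT_MORE


@dataclass(frozen=True)
class PairedCategoryCounts:
    """Parent-more / Doctor-more / Equal tallies for one scope."""

    scope: str
    n_parent_more: int
    n_doctor_more: int
    n_equal: int

    @property
    def n(self) -> int:
        return self.n_parent_more + self.n_doctor_more + self.n_equal


@dataclass
class TestResult:
    family: str
    scope: str
    statistic: float
    p_raw: float
    p_adjusted: Optional[float]
    method: str
    n: int
    extra: dict = field(default_factory=dict)


def mcnemar_test(b: int, c: int, continuity: bool = True) -> tuple[float, float]:
    """McNemar's chi-square on the two discordant counts.

    ``b`` and ``c`` are the Parent-more and Doctor-more counts; concordant
    (Equal) pairs are excluded by construction.  With ``continuity`` the
    statistic is (|b-c|-1)^2/(b+c), otherwise (b-c)^2/(b+c); p is the
    chi-square(1) upper tail.
    """
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    if b + c == 0:
        raise UndefinedTestError("McNemar undefined: no discordant pairs")
    k = 1.0 if continuity else 0.0
    stat = (abs(b - c) - k) ** 2 / (b + c)
    return float(stat), float(sps.chi2.sf(stat, df=1))


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def holm_adjust(p: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(ranked), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise DegenerateGroupError("need at least two groups")
    arrays = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if a.size < 2:
            raise DegenerateGroupError(f"group {i} has fewer than 2 observations")
        if np.var(a, ddof=1) <= 0:
            raise DegenerateGroupError(f"group {i} has zero variance")
        arrays.append(a)
    return arrays


def welch_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns (F, df1, df2, p).  For two groups, F equals the square of the
    Welch two-sample t statistic and df2 equals the Welch-Satterthwaite df.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n = np.array([a.size for a in arrays], dtype=float)
    means = np.array([a.mean() for a in arrays])
    variances = np.array([a.var(ddof=1) for a in arrays])
    w = n / variances
    w_total = w.sum()
    grand = (w * means).sum() / w_total
    numerator = (w * (means - grand) ** 2).sum() / (k - 1)
    lam = ((1 - w / w_total) ** 2 / (n - 1)).sum()
    denominator = 1 + 2 * (k - 2) * lam / (k**2 - 1)
    f_stat = numerator / denominator
    df1 = float(k - 1)
    df2 = (k**2 - 1) / (3 * lam)
    p = float(sps.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, float(df2), p


def pairwise_welch_holm(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    family: str = "pairwise",
) -> list[TestResult]:
    """All unordered-pair Welch t-tests with Holm adjustment across the family."""
    arrays = _check_groups(groups)
    if labels is None:
        labels = [str(i) for i in range(len(arrays))]
    results: list[TestResult] = []
    raw: list[float] = []
    for (i, a), (j, b) in combinations(enumerate(arrays), 2):
        t, p = sps.ttest_ind(a, b, equal_var=False)
        raw.append(float(p))
        results.append(
            TestResult(
                family=family,
                scope=f"{labels[i]} vs {labels[j]}",
                statistic=float(t),
                p_raw=float(p),
                p_adjusted=None,
                method="Welch t (Holm)",
                n=int(a.size + b.size),
            )
        )
    for r, p_adj in zip(results, holm_adjust(raw)):
        r.p_adjusted = p_adj
    return results


def counts_from_scores(
    scores: pd.DataFrame, value: str = "quantity"
) -> dict[str, PairedCategoryCounts]:
    """Tally Parent-more/Doctor-more/Equal per scope from a score table."""
    col = f"{value}_category"
    out: dict[str, PairedCategoryCounts] = {}
    for scope, sub in scores.groupby("scope", sort=True):
        cats = sub[col]
        n_parent = int((cats == PARENT_MORE).sum())
        n_doctor = int((cats == DOCTOR_MORE).sum())
        out[scope] = PairedCategoryCounts(
            scope=str(scope),
            n_parent_more=n_parent,
            n_doctor_more=n_doctor,
            n_equal=int(len(cats) - n_parent - n_doctor),
        )
    return out


def mcnemar_family(
    counts: Iterable[PairedCategoryCounts],
    family: str,
    continuity: bool = True,
) -> list[TestResult]:
    """McNemar per scope with BH adjustment across the family.

    Scopes with no discordant pairs are reported with NaN statistic and are
    excluded from the adjustment rather than aborting the family.
    """
    results: list[TestResult] = []
    testable: list[TestResult] = []
    raw: list[float] = []
    for cc in counts:
        try:
            stat, p = mcnemar_test(cc.n_parent_more, cc.n_doctor_more, continuity)
        except UndefinedTestError:
            results.append(
                TestResult(
                    family=family,
                    scope=cc.scope,
                    statistic=float("nan"),
                    p_raw=float("nan"),
                    p_adjusted=None,
                    method="McNemar chi2 (undefined)",
                    n=cc.n,
                    extra={"b": cc.n_parent_more, "c": cc.n_doctor_more},
                )
            )
            continue
        r = TestResult(
            family=family,
            scope=cc.scope,
            statistic=stat,
            p_raw=p,
            p_adjusted=None,
            method="McNemar chi2 (BH)",
            n=cc.n,
            extra={"b": cc.n_parent_more, "c": cc.n_doctor_more},
        )
        results.append(r)
        testable.append(r)
        raw.append(p)
    for r, p_adj in zip(testable, bh_adjust(raw)):
        r.p_adjusted = p_adj
    return results


def results_to_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "family": r.family,
                "scope": r.scope,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "method": r.method,
                "n": r.n,
                **{k: v for k, v in r.extra.items()},
            }
        )
    return pd.DataFrame(rows)
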