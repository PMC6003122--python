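"""Per-variable group comparisons with automatic test selection.

For each variable, the groups' non-missing observations are tested for
normality (Shapiro-Wilk at 0.05, per group); a parametric test is used only
when every group passes and has n >= 5, otherwise the rank-based
alternative:

===========  =================  =====================
groups       parametric         non-parametric
===========  =================  =====================
2            Welch t-test       Mann-Whitney U
3 or more    one-way ANOVA      Kruskal-Wallis
===========  =================  =====================

The Welch (unequal-variance) t-test is used deliberately: group sizes are
typically unbalanced (10 vs 35).  The Mann-Whitney statistic reported is the
U of the first group in sorted-label order (so complete separation with the
first group smaller gives U = 0).  Summaries are mean +/- SD for parametric
tests and median [IQR] otherwise.  Raw two-tailed p-values are flagged at
``alpha`` with no multiple-testing correction across variables — the report
states this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import CohortTable

__all__ = ["GroupTestResult", "GroupComparison", "compare_groups",
           "results_to_frame"]

_SHAPIRO_ALPHA = 0.05
_MIN_PARAMETRIC_N = 5


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of one variable's across-group comparison."""

    variable: str
    test_name: str  # anova | kruskal_wallis | t_test | mann_whitney | untestable
    statistic: float
    p_value: float
    per_group_summary: tuple[tuple[str, str], ...]
    n_per_group: tuple[tuple[str, int], ...]
    significant: bool
    reason: str = ""

    @property
    def testable(self) -> bool:
        return self.test_name != "untestable"


def _summaries(samples: dict[str, np.ndarray], parametric: bool):
    out = []
    for g, x in samples.items():
        if x.size == 0:
            out.append((g, "NA"))
        elif parametric:
            out.append((g, f"{x.mean():.2f} +/- {x.std(ddof=1):.2f}"))
        else:
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            out.append((g, f"{med:.2f} [{q1:.2f}-{q3:.2f}]"))
    return tuple(out)


def _all_normal(samples: dict[str, np.ndarray]) -> bool:
    for x in samples.values():
        if x.size < _MIN_PARAMETRIC_N:
            return False
        if np.all(x == x[0]):
            return False
        if stats.shapiro(x).pvalue < _SHAPIRO_ALPHA:
            return False
    return True


class GroupComparison(BaseEstimator):
    """Across-group comparison screen over all variables of a cohort.

    Parameters
    ----------
    alpha : float, default 0.05
        Two-tailed significance level for flagging.
    min_group_n : int, default 3
        Minimum non-missing observations per group for a variable to be
        testable; variables below it are reported as untestable, never
        silently dropped.
    parametric : {"auto", "always", "never"}, default "auto"
        "auto" applies the Shapiro-Wilk gate; the other values force one
        test family (useful for sensitivity analyses).

    Attributes (after fit): ``results_`` (list of :class:`GroupTestResult`),
    ``groups_`` (sorted labels).
    """

    def __init__(self, alpha: float = 0.05, min_group_n: int = 3,
                 parametric: str = "auto"):
        self.alpha = alpha
        self.min_group_n = min_group_n
        self.parametric = parametric

    def fit(self, X, y=None) -> "GroupComparison":
        if isinstance(X, CohortTable):
            frame, labels = X.data, X.groups
        else:
            if y is None:
                raise ValueError("y (group labels) required for a DataFrame")
            frame = pd.DataFrame(X)
            labels = pd.Series(np.asarray(y), index=frame.index)
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.parametric not in ("auto", "always", "never"):
            raise ValueError(f"unknown parametric policy {self.parametric!r}")
        self.groups_ = sorted(labels.astype(str).unique())
        if len(self.groups_) < 2:
            raise ValueError("need at least 2 groups to compare")
        self.results_ = [
            self._test_variable(str(col), frame[col].to_numpy(dtype=float),
                                labels.astype(str).to_numpy())
            for col in frame.columns
        ]
        return self

    def _test_variable(self, name: str, values: np.ndarray,
                       labels: np.ndarray) -> GroupTestResult:
        samples = {
            g: values[(labels == g) & np.isfinite(values)]
            for g in self.groups_
        }
        ns = tuple((g, int(x.size)) for g, x in samples.items())
        small = [g for g, x in samples.items() if x.size < self.min_group_n]
        if small:
            return GroupTestResult(
                name, "untestable", np.nan, np.nan,
                _summaries(samples, False), ns, False,
                reason=f"insufficient n in groups: {small}",
            )
        pooled = np.concatenate(list(samples.values()))
        if np.all(pooled == pooled[0]):
            return GroupTestResult(
                name, "untestable", np.nan, np.nan,
                _summaries(samples, False), ns, False,
                reason="constant in all groups",
            )
        if self.parametric == "auto":
            parametric = _all_normal(samples)
        else:
            parametric = self.parametric == "always"
        arrays = list(samples.values())
        if len(arrays) == 2:
            if parametric:
                res = stats.ttest_ind(*arrays, equal_var=False)
                test = "t_test"
            else:
                res = stats.mannwhitneyu(*arrays, alternative="two-sided")
                test = "mann_whitney"
        else:
            if parametric:
                res = stats.f_oneway(*arrays)
                test = "anova"
            else:
                res = stats.kruskal(*arrays)
                test = "kruskal_wallis"
        stat, p = float(res.statistic), float(res.pvalue)
        return GroupTestResult(
            name, test, stat, p, _summaries(samples, parametric), ns,
            significant=bool(p < self.alpha),
        )

    def to_frame(self, levels=None) -> pd.DataFrame:
        rows = []
        for r in self.results_:
            row = {
                "variable": r.variable,
                "level": (levels or {}).get(r.variable, ""),
                "test": r.test_name,
                "statistic": r.statistic,
                "p": r.p_value,
                "significant": r.significant,
                "reason": r.reason,
            }
            for g, s in r.per_group_summary:
                row[f"summary_{g}"] = s
            for g, n in r.n_per_group:
                row[f"n_{g}"] = n
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame.attrs["note"] = (
            "raw two-tailed p-values, no multiple-testing correction; "
            f"flagged at alpha={self.alpha}"
        )
        return frame


def compare_groups(cohort: CohortTable, alpha: float = 0.05) -> list[GroupTestResult]:
    """Compare every cohort variable across groups (see :class:`GroupComparison`)."""
    return GroupComparison(alpha=alpha).fit(cohort).results_


def results_to_frame(cohort: CohortTable, results=None,
                     alpha: float = 0.05) -> pd.DataFrame:
    est = GroupComparison(alpha=alpha).fit(cohort)
    return est.to_frame(levels=cohort.levels)
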