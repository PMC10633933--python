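"""Multi-survey summarization: corpus percentile tables, subgroup-exclusion
sensitivity, mean-SD correlation, and paired child/WRA comparisons.

The corpus summary treats each survey's distribution parameters (mean,
median, anemia prevalence, SD, skewness G1, excess kurtosis G2) as one
observation and reports their mean, SD and a fixed quantile ladder across
surveys. Sensitivity variants re-run the summary excluding a subgroup of
surveys (e.g. one country) via a generic predicate. The paired comparison
matches surveys that measured both children and WRA at the same site and
tests the child-minus-WRA difference of a survey-level statistic with a
paired t interval (Wilcoxon signed-rank available as an alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distribution_stats import SurveyStats, quantile
from .survey_model import Group

#: Quantile ladder reported for each statistic, top to bottom.
QUANTILE_ROWS = [
    ("max", 1.0), ("p97.5", 0.975), ("p90", 0.90), ("p75", 0.75),
    ("p50", 0.50), ("p25", 0.25), ("p10", 0.10), ("p2.5", 0.025),
    ("min", 0.0),
]

#: Survey-level statistics summarized across the corpus.
STATISTICS = ["mean", "median", "anemia_pct", "sd", "skewness", "kurtosis"]

_FIELD = {
    "mean": "mean_gdl", "median": "median_gdl", "anemia_pct": "anemia_pct",
    "sd": "sd_gdl", "skewness": "skewness_g1", "kurtosis": "kurtosis_g2",
}


@dataclass(frozen=True)
class CorpusSummaryTable:
    """Across-survey summary of survey-level statistics for one group.

    ``table`` has statistics as columns and rows mean, sd, then the
    quantile ladder from max down to min.
    """

    group: Group
    label: str
    n_surveys: int
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.4f")


@dataclass(frozen=True)
class PairedComparison:
    """Paired child-vs-WRA comparison of one survey-level statistic."""

    statistic: str
    n_pairs: int
    mean_child: float
    sd_child: float
    mean_wra: float
    sd_wra: float
    difference: float  # child - wra
    ci95: tuple[float, float]
    p_value: float
    method: str = "paired-t"

    def as_row(self) -> dict:
        return {
            "statistic": self.statistic, "n_pairs": self.n_pairs,
            "mean_child": self.mean_child, "sd_child": self.sd_child,
            "mean_wra": self.mean_wra, "sd_wra": self.sd_wra,
            "difference": self.difference,
            "ci95_low": self.ci95[0], "ci95_high": self.ci95[1],
            "p_value": self.p_value, "method": self.method,
        }


def summarize_corpus(
    stats_list: Sequence[SurveyStats],
    group: Group,
    exclude_filter: Callable[[SurveyStats], bool] | None = None,
    *,
    label: str = "all surveys",
    quantile_method: str = "linear",
) -> CorpusSummaryTable:
    """Build the across-survey percentile summary for one group.

    When ``exclude_filter`` is given, surveys for which it returns True are
    dropped before summarizing (callers typically emit both the unfiltered
    and the filtered variant side by side).
    """
    rows = [s for s in stats_list if s.group is group]
    if exclude_filter is not None:
        rows = [s for s in rows if not exclude_filter(s)]
    if len(rows) < 2:
        raise ValueError(
            f"too few {group.value} surveys ({len(rows)}) for corpus summary "
            f"[{label}]"
        )
    data = {
        stat: np.array([getattr(s, _FIELD[stat]) for s in rows], dtype=float)
        for stat in STATISTICS
    }
    index = ["mean", "sd"] + [name for name, _ in QUANTILE_ROWS]
    table = pd.DataFrame(index=index, columns=STATISTICS, dtype=float)
    for stat, x in data.items():
        x = x[~np.isnan(x)]
        table.loc["mean", stat] = float(np.mean(x))
        table.loc["sd", stat] = float(np.std(x, ddof=1))
        for name, p in QUANTILE_ROWS:
            table.loc[name, stat] = float(quantile(x, p, quantile_method))
    return CorpusSummaryTable(group=group, label=label, n_surveys=len(rows),
                              table=table)


def spearman_rho(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the t-approximation on n-2 degrees of freedom.
    Constant input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman_rho requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def paired_compare(
    stats_child: Sequence[SurveyStats],
    stats_wra: Sequence[SurveyStats],
    statistic: str,
    *,
    method: str = "paired-t",
) -> PairedComparison:
    """Compare a survey-level statistic between matched child/WRA surveys.

    Surveys are matched on survey_id; the difference is child minus WRA.
    ``method`` is "paired-t" (default; two-sided 95% t interval on the
    differences) or "wilcoxon" (signed-rank p-value; the interval is still
    the t interval, reported for location).
    """
    fld = _FIELD[statistic] if statistic in _FIELD else statistic
    child_by_id = {s.survey_id: s for s in stats_child if s.group is Group.CHILD}
    wra_by_id = {s.survey_id: s for s in stats_wra if s.group is Group.WRA}
    ids = sorted(set(child_by_id) & set(wra_by_id))
    if not ids:
        raise ValueError("no matched survey pairs")
    c = np.array([getattr(child_by_id[i], fld) for i in ids], dtype=float)
    w = np.array([getattr(wra_by_id[i], fld) for i in ids], dtype=float)
    keep = ~(np.isnan(c) | np.isnan(w))
    c, w = c[keep], w[keep]
    n = c.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    d = c - w
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d <= 1e-10 * max(1.0, abs(mean_d)):  # constant differences
        ci = (mean_d, mean_d)
        p = math.nan
    else:
        se = sd_d / math.sqrt(n)
        tcrit = float(sps.t.ppf(0.975, n - 1))
        ci = (mean_d - tcrit * se, mean_d + tcrit * se)
        if method == "wilcoxon":
            p = float(sps.wilcoxon(d).pvalue)
        else:
            p = float(sps.ttest_rel(c, w).pvalue)
    return PairedComparison(
        statistic=statistic, n_pairs=n,
        mean_child=float(c.mean()), sd_child=float(c.std(ddof=1)),
        mean_wra=float(w.mean()), sd_wra=float(w.std(ddof=1)),
        difference=mean_d, ci95=ci, p_value=p, method=method,
    )


def mean_sd_correlation(
    stats_list: Sequence[SurveyStats],
    exclude_filter: Callable[[SurveyStats], bool] | None = None,
) -> tuple[float, float]:
    """Spearman correlation between survey-level mean and SD of Hb."""
    rows = [s for s in stats_list if exclude_filter is None or not exclude_filter(s)]
    if len(rows) < 3:
        raise ValueError("mean_sd_correlation requires >= 3 surveys")
    means = [s.mean_gdl for s in rows]
    sds = [s.sd_gdl for s in rows]
    return spearman_rho(means, sds)


def paired_statistic_correlation(
    stats_child: Sequence[SurveyStats],
    stats_wra: Sequence[SurveyStats],
    statistic: str,
) -> tuple[float, float]:
    """Spearman correlation of a statistic across matched child/WRA surveys."""
    fld = _FIELD[statistic] if statistic in _FIELD else statistic
    child_by_id = {s.survey_id: s for s in stats_child if s.group is Group.CHILD}
    wra_by_id = {s.survey_id: s for s in stats_wra if s.group is Group.WRA}
    ids = sorted(set(child_by_id) & set(wra_by_id))
    c = [getattr(child_by_id[i], fld) for i in ids]
    w = [getattr(wra_by_id[i], fld) for i in ids]
    return spearman_rho(c, w)


def stats_to_frame(stats_list: Sequence[SurveyStats]) -> pd.DataFrame:
    """Survey summaries as a tidy DataFrame in the fixed column order."""
    from .distribution_stats import STATS_COLUMNS

    rows = [s.as_row() | {"country": s.country, "site": s.site, "year": s.year}
            for s in stats_list]
    return pd.DataFrame(rows, columns=STATS_COLUMNS + ["country", "site", "year"])
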