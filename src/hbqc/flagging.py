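"""Plausibility exclusion and multi-cutoff outlier tabulation.

Hb values outside a plausibility range (default 4.0-18.0 g/dL, bounds
kept) are treated as probable gross errors. This module excludes them
before moment estimation and tabulates, across a grid of cutoffs, the
percentage of records beyond each cutoff and the percentage of surveys
falling in three outlier-prevalence categories: no outliers, 0-1%
(interpreted as (0, 1]), and > 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True, slots=True)
class ExclusionPolicy:
    """Plausibility range; values strictly beyond the bounds are excluded."""

    low: float = 4.0
    high: float = 18.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("exclusion range must satisfy low < high")


@dataclass(frozen=True)
class OutlierCutoffSet:
    """Cutoff grid for the outlier tabulation (strict comparisons)."""

    low_cutoffs: tuple[float, ...] = (4.0, 5.0, 6.0)
    high_cutoffs: tuple[float, ...] = (16.0, 17.0, 18.0)

    def __post_init__(self) -> None:
        if max(self.low_cutoffs) >= min(self.high_cutoffs):
            raise ValueError("every low cutoff must be below every high cutoff")

    def columns(self) -> list[tuple[str, float | None, str]]:
        """(label, cutoff, side) for each tabulated column, incl. combined."""
        cols: list[tuple[str, float | None, str]] = []
        cols += [(f"< {c:g} g/dL", c, "below") for c in self.low_cutoffs]
        cols += [(f"> {c:g} g/dL", c, "above") for c in self.high_cutoffs]
        lo, hi = min(self.low_cutoffs), max(self.high_cutoffs)
        cols.append((f"< {lo:g} or > {hi:g} g/dL", None, "combined"))
        return cols


class OutlierCategory(str, Enum):
    NONE = "none"    # exactly 0% outliers
    UPTO1 = "upto1"  # (0, 1]%
    GT1 = "gt1"      # > 1%


@dataclass(frozen=True)
class FlagSummary:
    """Record- and survey-level outlier percentages per cutoff column.

    ``record_pct[label]`` pools all records (each record weighted equally);
    ``survey_category_pct[label]`` maps each category to the percentage of
    surveys in it, summing to 100 up to rounding.
    """

    group: str
    n_records: int
    n_surveys: int
    record_pct: dict[str, float] = field(default_factory=dict)
    survey_category_pct: dict[str, dict[OutlierCategory, float]] = field(
        default_factory=dict
    )

    def to_frame(self) -> pd.DataFrame:
        """Render as a table: cutoffs as columns, categories as rows."""
        rows = {
            f"% of records ({self.group})": self.record_pct,
            "% surveys, no outliers": {
                k: v[OutlierCategory.NONE] for k, v in self.survey_category_pct.items()
            },
            "% surveys, 0-1% outliers": {
                k: v[OutlierCategory.UPTO1] for k, v in self.survey_category_pct.items()
            },
            "% surveys, >1% outliers": {
                k: v[OutlierCategory.GT1] for k, v in self.survey_category_pct.items()
            },
        }
        return pd.DataFrame(rows).T[list(self.record_pct)]


def apply_exclusion(
    values: Sequence[float] | np.ndarray, policy: ExclusionPolicy | None = None
) -> tuple[np.ndarray, int, int]:
    """Split values into (kept, n_excluded_low, n_excluded_high).

    Kept = {x : low <= x <= high}; exclusion is strict beyond the bounds,
    so values exactly at 4.0 or 18.0 g/dL stay in the analysis.
    """
    policy = policy or ExclusionPolicy()
    x = np.asarray(values, dtype=float)
    n_low = int(np.sum(x < policy.low))
    n_high = int(np.sum(x > policy.high))
    kept = x[(x >= policy.low) & (x <= policy.high)]
    return kept, n_low, n_high


def outlier_fraction(
    values: Sequence[float] | np.ndarray, cutoff: float, side: str
) -> float:
    """Percentage of values strictly beyond ``cutoff`` on the given side."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("outlier_fraction undefined for empty input")
    if side == "below":
        count = int(np.sum(x < cutoff))
    elif side == "above":
        count = int(np.sum(x > cutoff))
    else:
        raise ValueError(f"side must be 'below' or 'above', got {side!r}")
    return 100.0 * count / x.size


def categorize_survey_outliers(pct: float) -> OutlierCategory:
    """Map a survey's outlier percentage to {none, (0,1], >1} categories."""
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage out of range: {pct}")
    if pct == 0:
        return OutlierCategory.NONE
    if pct <= 1.0:
        return OutlierCategory.UPTO1
    return OutlierCategory.GT1


def _combined_pct(x: np.ndarray, low: float, high: float) -> float:
    return 100.0 * int(np.sum((x < low) | (x > high))) / x.size


def tabulate_flags(
    surveys_values: Sequence[np.ndarray],
    cutoffs: OutlierCutoffSet | None = None,
    *,
    group: str = "all",
) -> FlagSummary:
    """Tabulate outliers over a corpus; one valid-value array per survey.

    Record-level percentages pool all records with equal weight; the
    survey-level categorization is computed per survey then expressed as a
    percentage of surveys. Survey order does not affect the result.
    """
    cutoffs = cutoffs or OutlierCutoffSet()
    arrays = [np.asarray(v, dtype=float) for v in surveys_values]
    if not arrays or any(a.size == 0 for a in arrays):
        raise ValueError("tabulate_flags requires >= 1 survey, none empty")
    pooled = np.concatenate(arrays)
    n_surveys = len(arrays)
    lo, hi = min(cutoffs.low_cutoffs), max(cutoffs.high_cutoffs)

    record_pct: dict[str, float] = {}
    cat_pct: dict[str, dict[OutlierCategory, float]] = {}
    for label, cutoff, side in cutoffs.columns():
        if side == "combined":
            record_pct[label] = _combined_pct(pooled, lo, hi)
            per_survey = [_combined_pct(a, lo, hi) for a in arrays]
        else:
            record_pct[label] = outlier_fraction(pooled, cutoff, side)
            per_survey = [outlier_fraction(a, cutoff, side) for a in arrays]
        counts = {c: 0 for c in OutlierCategory}
        for pct in per_survey:
            counts[categorize_survey_outliers(pct)] += 1
        cat_pct[label] = {c: 100.0 * k / n_surveys for c, k in counts.items()}

    return FlagSummary(
        group=group,
        n_records=int(pooled.size),
        n_surveys=n_surveys,
        record_pct=record_pct,
        survey_category_pct=cat_pct,
    )
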