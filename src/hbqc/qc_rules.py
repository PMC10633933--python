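"""Per-survey QC rule engine and percentile-based threshold derivation.

A survey's Hb distribution is flagged for quality investigation when any
of the following hold: skewness G1 above +0.2, excess kurtosis G2 below
-0.5, SD outside 1.1-1.55 g/dL (children) or 1.1-1.65 g/dL (non-pregnant
WRA), or more than 1% of values outside the 4.0-18.0 g/dL plausibility
range. The SD upper bounds correspond to the 90th percentile of
survey-level SD in a large reference corpus of field surveys, rounded to
the nearest 0.05 g/dL; :func:`derive_thresholds` recomputes such bounds
from any corpus of survey summaries.

Boundary semantics: values exactly at a bound pass (the rules use strict
inequalities: "above +0.2", "below -0.5", SD strictly outside its range,
flag percentage strictly above 1%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .distribution_stats import SurveyStats, quantile
from .flagging import ExclusionPolicy
from .survey_model import Group


class QCFlag(str, Enum):
    SKEW_HIGH = "SKEW_HIGH"
    KURT_LOW = "KURT_LOW"
    SD_LOW = "SD_LOW"
    SD_HIGH = "SD_HIGH"
    FLAG_PCT_HIGH = "FLAG_PCT_HIGH"


class Verdict(str, Enum):
    PASS = "pass"
    INVESTIGATE = "investigate"
    INSUFFICIENT = "insufficient data"


@dataclass(frozen=True)
class QCRuleSet:
    """Threshold constants for the per-survey quality rules."""

    skew_max: float = 0.2
    kurt_min: float = -0.5
    sd_range_child: tuple[float, float] = (1.1, 1.55)
    sd_range_wra: tuple[float, float] = (1.1, 1.65)
    flag_pct_max: float = 1.0
    exclusion: ExclusionPolicy = field(default_factory=ExclusionPolicy)

    def __post_init__(self) -> None:
        for lo, hi in (self.sd_range_child, self.sd_range_wra):
            if not lo < hi:
                raise ValueError("SD range must satisfy lower < upper")
        if not 0 < self.flag_pct_max < 100:
            raise ValueError("flag_pct_max must be in (0, 100)")

    def sd_range(self, group: Group) -> tuple[float, float]:
        return self.sd_range_child if group is Group.CHILD else self.sd_range_wra

    def to_dict(self) -> dict:
        return {
            "skew_max": self.skew_max,
            "kurt_min": self.kurt_min,
            "sd_range_child": list(self.sd_range_child),
            "sd_range_wra": list(self.sd_range_wra),
            "flag_pct_max": self.flag_pct_max,
            "exclusion": {"low": self.exclusion.low, "high": self.exclusion.high},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "QCRuleSet":
        kwargs: dict = {}
        if "skew_max" in d:
            kwargs["skew_max"] = float(d["skew_max"])
        if "kurt_min" in d:
            kwargs["kurt_min"] = float(d["kurt_min"])
        if "sd_range_child" in d:
            kwargs["sd_range_child"] = tuple(map(float, d["sd_range_child"]))
        if "sd_range_wra" in d:
            kwargs["sd_range_wra"] = tuple(map(float, d["sd_range_wra"]))
        if "flag_pct_max" in d:
            kwargs["flag_pct_max"] = float(d["flag_pct_max"])
        if "exclusion" in d:
            e = d["exclusion"]
            kwargs["exclusion"] = ExclusionPolicy(float(e["low"]), float(e["high"]))
        return cls(**kwargs)


@dataclass(frozen=True)
class QCReport:
    """Verdict for one survey, with the triggered rules and values compared."""

    survey_id: str
    group: Group
    triggered: frozenset[QCFlag]
    verdict: Verdict
    rule_values: dict

    def to_text(self) -> str:
        lines = [f"survey {self.survey_id} ({self.group.value}): {self.verdict.value}"]
        for flag in sorted(self.triggered, key=lambda f: f.value):
            lines.append(f"  - {flag.value}")
        for k, v in self.rule_values.items():
            lines.append(f"    {k} = {v}")
        return "\n".join(lines)


def evaluate_qc(stats: SurveyStats, rules: QCRuleSet | None = None) -> QCReport:
    """Apply the QC rules to one survey summary.

    Rules are evaluated independently (flags, not a composite score); the
    verdict is "investigate" iff at least one rule triggers. Summaries with
    undefined moments (n < 4 or degenerate) get verdict "insufficient data".
    """
    rules = rules or QCRuleSet()
    values = {
        "sd_gdl": stats.sd_gdl,
        "skewness_g1": stats.skewness_g1,
        "kurtosis_g2": stats.kurtosis_g2,
        "flag_pct": stats.flag_pct,
    }
    if any(isinstance(v, float) and math.isnan(v) for v in values.values()):
        return QCReport(stats.survey_id, stats.group, frozenset(),
                        Verdict.INSUFFICIENT, values)
    triggered = set()
    if stats.skewness_g1 > rules.skew_max:
        triggered.add(QCFlag.SKEW_HIGH)
    if stats.kurtosis_g2 < rules.kurt_min:
        triggered.add(QCFlag.KURT_LOW)
    sd_lo, sd_hi = rules.sd_range(stats.group)
    if stats.sd_gdl < sd_lo:
        triggered.add(QCFlag.SD_LOW)
    if stats.sd_gdl > sd_hi:
        triggered.add(QCFlag.SD_HIGH)
    if stats.flag_pct > rules.flag_pct_max:
        triggered.add(QCFlag.FLAG_PCT_HIGH)
    verdict = Verdict.INVESTIGATE if triggered else Verdict.PASS
    return QCReport(stats.survey_id, stats.group, frozenset(triggered),
                    verdict, values)


def round_to_nearest(value: float, step: float = 0.05) -> float:
    """Round to the nearest multiple of ``step``; ties round away from zero."""
    if step <= 0:
        raise ValueError("step must be positive")
    sign = -1.0 if value < 0 else 1.0
    # small epsilon keeps exact .5 ties (decimal inputs) from landing below
    # the tie point after binary rounding error
    k = math.floor(abs(value) / step + 0.5 + 1e-9)
    return round(sign * k * step, 10)


def derive_thresholds(
    corpus_stats: Sequence[SurveyStats],
    p_low: float = 0.025,
    p_high: float = 0.90,
    exclude: Callable[[SurveyStats], bool] | None = None,
    *,
    min_surveys: int = 20,
    step: float = 0.05,
    quantile_method: str = "linear",
    base_rules: QCRuleSet | None = None,
) -> QCRuleSet:
    """Derive per-group SD plausibility ranges from corpus percentiles.

    For each group, takes the p_low and p_high quantiles of the
    survey-level SDs (after dropping surveys matching ``exclude``, e.g. a
    suspect country) and rounds each to the nearest ``step`` (0.05 g/dL).
    Returns a candidate rule set with the derived SD ranges substituted
    into ``base_rules``. Refuses when fewer than ``min_surveys`` remain in
    either group.
    """
    base = base_rules or QCRuleSet()
    kept = [s for s in corpus_stats if exclude is None or not exclude(s)]
    ranges: dict[Group, tuple[float, float]] = {}
    for group in (Group.CHILD, Group.WRA):
        sds = np.array(
            [s.sd_gdl for s in kept if s.group is group and not math.isnan(s.sd_gdl)]
        )
        if sds.size < min_surveys:
            raise ValueError(
                f"too few {group.value} surveys after exclusion "
                f"({sds.size} < {min_surveys}); cannot derive thresholds"
            )
        lo = round_to_nearest(float(quantile(sds, p_low, quantile_method)), step)
        hi = round_to_nearest(float(quantile(sds, p_high, quantile_method)), step)
        ranges[group] = (lo, hi) if lo < hi else (lo, lo + step)
    return replace(
        base, sd_range_child=ranges[Group.CHILD], sd_range_wra=ranges[Group.WRA]
    )


def run_qc(
    stats_list: Iterable[SurveyStats], rules: QCRuleSet | None = None
) -> list[QCReport]:
    """Evaluate the rule set over a corpus of survey summaries."""
    rules = rules or QCRuleSet()
    return [evaluate_qc(s, rules) for s in stats_list]
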