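"""Per-survey distribution characterization.

The survey-level summary consists of the mean, median, standard deviation,
bias-corrected skewness (G1) and excess kurtosis (G2) of Hb, computed on
values inside the plausibility range (default 4.0-18.0 g/dL), plus total
anemia prevalence and the percentage of implausible ("flagged") values.

G1 and G2 are the bias-adjusted estimators built from the sample central
moments m_r = (1/n) * sum (x_i - xbar)^r:

    g1 = m3 / m2^(3/2)          G1 = g1 * sqrt(n(n-1)) / (n-2)
    g2 = m4 / m2^2 - 3          G2 = ((n+1) g2 + 6) (n-1) / ((n-2)(n-3))

G2 is an *excess* kurtosis (fourth standardized moment minus 3), centered
at zero under a normal distribution; both estimators are unbiased under
normality. Skewness requires n >= 3, kurtosis n >= 4, and both require a
non-degenerate sample (m2 > 0); otherwise they are reported unavailable
(NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .anemia import AnemiaRules, anemia_prevalence
from .flagging import ExclusionPolicy, apply_exclusion
from .survey_model import Group, Survey

#: Fixed column order for serialized survey summaries.
STATS_COLUMNS = [
    "survey_id", "group", "n", "mean", "median", "sd",
    "skewness_g1", "kurtosis_g2", "anemia_pct", "flag_pct",
]


@dataclass(frozen=True, slots=True)
class SurveyStats:
    """Distribution summary of one survey's plausibility-filtered Hb values.

    ``n`` counts the analyzed (in-range) values; ``flag_pct`` is the
    percentage of *valid* records outside the plausibility range, computed
    before that exclusion. Unavailable statistics are NaN.
    """

    survey_id: str
    group: Group
    n: int
    mean_gdl: float
    median_gdl: float
    sd_gdl: float
    skewness_g1: float
    kurtosis_g2: float
    anemia_pct: float
    flag_pct: float
    country: str = ""
    site: str = ""
    year: int | None = None

    def as_row(self) -> dict:
        return {
            "survey_id": self.survey_id,
            "group": self.group.value,
            "n": self.n,
            "mean": self.mean_gdl,
            "median": self.median_gdl,
            "sd": self.sd_gdl,
            "skewness_g1": self.skewness_g1,
            "kurtosis_g2": self.kurtosis_g2,
            "anemia_pct": self.anemia_pct,
            "flag_pct": self.flag_pct,
        }


def central_moment(values: Sequence[float] | np.ndarray, r: int) -> float:
    """r-th sample central moment m_r = (1/n) sum (x_i - xbar)^r."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("central_moment undefined for empty input")
    return float(np.mean((x - x.mean()) ** r))


def sample_sd(values: Sequence[float] | np.ndarray) -> float:
    """Sample standard deviation with the n-1 denominator; NaN if n < 2."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return math.nan
    return float(np.std(x, ddof=1))


def skewness_g1(values: Sequence[float] | np.ndarray) -> float:
    """Bias-adjusted sample skewness G1; NaN if n < 3 or the sample is constant."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        return math.nan
    m2 = central_moment(x, 2)
    if m2 <= 0:
        return math.nan
    g1 = central_moment(x, 3) / m2**1.5
    return g1 * math.sqrt(n * (n - 1)) / (n - 2)


def kurtosis_g2(values: Sequence[float] | np.ndarray) -> float:
    """Bias-adjusted excess kurtosis G2; NaN if n < 4 or the sample is constant."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        return math.nan
    m2 = central_moment(x, 2)
    if m2 <= 0:
        return math.nan
    g2 = central_moment(x, 4) / m2**2 - 3.0
    return ((n + 1) * g2 + 6.0) * (n - 1) / ((n - 2) * (n - 3))


def quantile(
    values: Sequence[float] | np.ndarray,
    p: float | Sequence[float],
    method: str = "linear",
) -> float | np.ndarray:
    """Order-statistic quantile under a configurable interpolation rule.

    ``method`` is any definition numpy.quantile accepts; the default
    "linear" is the common linear-interpolation rule (Hyndman-Fan type 7).
    p=0 gives the minimum and p=1 the maximum under every definition.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return math.nan
    out = np.quantile(x, p, method=method)
    return float(out) if np.isscalar(p) else out


def summarize_survey(
    survey: Survey,
    exclusion: ExclusionPolicy | None = None,
    anemia_rules: AnemiaRules | None = None,
    *,
    quantile_method: str = "linear",
) -> SurveyStats:
    """Compute a survey's :class:`SurveyStats`.

    All moments, the median and anemia prevalence are computed on valid
    records inside the plausibility range; ``flag_pct`` is computed on all
    valid records before that exclusion. A survey with no in-range values
    raises ValueError (reported upstream with its reason).
    """
    exclusion = exclusion or ExclusionPolicy()
    anemia_rules = anemia_rules or AnemiaRules()
    valid = survey.valid_values()
    if valid.size == 0:
        raise ValueError(f"survey {survey.survey_id!r}: no valid Hb values")
    kept, n_low, n_high = apply_exclusion(valid, exclusion)
    flag_pct = 100.0 * (n_low + n_high) / valid.size
    if kept.size == 0:
        raise ValueError(
            f"survey {survey.survey_id!r}: no Hb values inside "
            f"[{exclusion.low}, {exclusion.high}] g/dL"
        )
    return SurveyStats(
        survey_id=survey.survey_id,
        group=survey.group,
        n=int(kept.size),
        mean_gdl=float(kept.mean()),
        median_gdl=float(quantile(kept, 0.5, method=quantile_method)),
        sd_gdl=sample_sd(kept),
        skewness_g1=skewness_g1(kept),
        kurtosis_g2=kurtosis_g2(kept),
        anemia_pct=anemia_prevalence(kept, survey.group, anemia_rules),
        flag_pct=flag_pct,
        country=survey.country,
        site=survey.site,
        year=survey.year,
    )
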