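"""WHO anemia classification and optional altitude adjustment of Hb.

Total anemia is Hb < 11.0 g/dL for children 6-59 months and < 12.0 g/dL
for non-pregnant women 15-49 years (WHO cutoffs at sea level). Survey data
normally arrive already altitude-adjusted; when they do not,
:func:`adjust_for_altitude` applies the CDC polynomial correction, which
lowers the observed Hb so that the sea-level cutoffs remain applicable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .survey_model import Group

#: meters -> thousands of feet
_M_TO_KFT = 0.0032808


@dataclass(frozen=True, slots=True)
class AnemiaRules:
    """Group-specific anemia cutoffs, g/dL (strict '<' comparison)."""

    cutoff_child: float = 11.0
    cutoff_wra: float = 12.0

    def __post_init__(self) -> None:
        if self.cutoff_child <= 0 or self.cutoff_wra <= 0:
            raise ValueError("anemia cutoffs must be positive")

    def cutoff(self, group: Group) -> float:
        if group is Group.CHILD:
            return self.cutoff_child
        if group is Group.WRA:
            return self.cutoff_wra
        raise ValueError(f"unknown group: {group!r}")


def adjust_for_altitude(hb_raw: float, altitude_m: float) -> float:
    """CDC altitude adjustment: subtract max(0, -0.032*A + 0.022*A^2) g/dL.

    A is altitude in thousands of feet. The polynomial is negative below
    about 1.45 kft (~440 m), where physiological compensation is
    negligible, so the adjustment is floored at zero: low altitude never
    inflates Hb. The correction is swappable (see
    :func:`make_altitude_adjuster`) because agencies publish tabulated
    variants of the same curve.
    """
    if altitude_m < 0:
        raise ValueError("altitude must be non-negative")
    a = altitude_m * _M_TO_KFT
    return hb_raw - max(0.0, -0.032 * a + 0.022 * a * a)


def make_altitude_adjuster(
    fn: Callable[[float, float], float] | None = None,
) -> Callable[[float, float], float]:
    """Return the configured adjustment function (default: CDC polynomial)."""
    return fn if fn is not None else adjust_for_altitude


def classify_anemia(
    hb: float, group: Group, rules: AnemiaRules | None = None
) -> bool:
    """True iff Hb is strictly below the group's cutoff."""
    rules = rules or AnemiaRules()
    return hb < rules.cutoff(group)


def anemia_prevalence(
    values: Sequence[float] | np.ndarray,
    group: Group,
    rules: AnemiaRules | None = None,
) -> float:
    """Percentage of values below the group cutoff (plausibility-filtered)."""
    rules = rules or AnemiaRules()
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("anemia_prevalence undefined for empty input")
    return 100.0 * float(np.mean(x < rules.cutoff(group)))
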