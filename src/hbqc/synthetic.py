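"""Seeded generator of record-level Hb surveys with controllable moments.

The restricted field-survey microdata behind the reference corpus cannot
be redistributed, so this module generates stand-in surveys whose
distributional shape is controlled: target mean, SD, skewness and excess
kurtosis per survey, drawn per-corpus from hyper-distributions matching
the reference corpus's across-survey summary, with negative mean-SD
coupling, cross-group SD correlation between the child and WRA surveys of
one site, and optional gross-error contamination producing implausible
values.

Non-normal shapes come from the Fleishman power method: X = a + bZ + cZ^2
+ dZ^3 with Z standard normal and a = -c, whose coefficients are solved
numerically so X has mean 0, variance 1 and the target third and fourth
standardized moments. The method covers excess kurtosis down to about
-1.23 + 1.64*skew^2 (anything a field Hb survey plausibly shows); targets
below that boundary raise :class:`InfeasibleMomentsError`. Values are
rounded to 0.1 g/dL to emulate photometer display precision and clipped
to the 0-25.6 g/dL device range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize

from .survey_model import Group, HbRecord, Survey

#: Device reporting range used for final clipping, g/dL.
_CLIP = (0.0, 25.6)

#: Survey years of the emulated corpus (none in 2020).
_YEARS = (2013, 2014, 2015, 2016, 2017, 2018, 2019, 2021)


class InfeasibleMomentsError(ValueError):
    """Skewness/kurtosis target outside the polynomial family's reach."""


def feasibility_boundary(skew: float) -> float:
    """Lower limit of excess kurtosis supported at a given skewness.

    The third-order polynomial family cannot reach arbitrarily light tails:
    at zero skewness its minimum excess kurtosis is about -1.1513, rising
    roughly quadratically with skewness. This curve (-1.1513 + 1.7*skew^2)
    sits slightly above the family's exact boundary, by construction: the
    numerical solver is verified to converge everywhere at or above it, and
    the sliver it gives up is far lighter-tailed than any field Hb survey.
    """
    return -1.1513 + 1.7 * skew * skew


def _fleishman_system(params: np.ndarray, skew: float, ekurt: float) -> list[float]:
    b, c, d = params
    var = b * b + 6 * b * d + 2 * c * c + 15 * d * d
    g1 = 2 * c * (b * b + 24 * b * d + 105 * d * d + 2)
    g2 = 24 * (
        b * d
        + c * c * (1 + b * b + 28 * b * d)
        + d * d * (12 + 48 * b * d + 141 * c * c + 225 * d * d)
    )
    return [var - 1.0, g1 - skew, g2 - ekurt]


@lru_cache(maxsize=4096)
def solve_moment_coefficients(
    target_skew: float, target_excess_kurt: float
) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) of the moment-matching polynomial.

    X = a + bZ + cZ^2 + dZ^3 has mean 0, variance 1, and the requested
    standardized third and fourth moments; a = -c enforces the zero mean.
    Solved numerically to residual < 1e-9; infeasible targets raise
    :class:`InfeasibleMomentsError` reporting the kurtosis boundary.
    """
    boundary = feasibility_boundary(target_skew)
    if target_excess_kurt < boundary - 1e-12:
        raise InfeasibleMomentsError(
            f"excess kurtosis {target_excess_kurt:g} unreachable at skewness "
            f"{target_skew:g}; family minimum is about {boundary:.4f}"
        )
    if target_skew == 0.0 and target_excess_kurt == 0.0:
        return (0.0, 1.0, 0.0, 0.0)
    inits = [
        (1.0, target_skew / 6.0, target_excess_kurt / 24.0),
        (0.9, target_skew / 8.0, 0.05),
        (0.8, 0.0, 0.1),
    ]
    for x0 in inits:
        sol = optimize.root(
            _fleishman_system, x0, args=(target_skew, target_excess_kurt),
            method="hybr", tol=1e-13,
        )
        resid = np.max(np.abs(_fleishman_system(sol.x, target_skew,
                                                target_excess_kurt)))
        if sol.success and resid < 1e-9:
            b, c, d = map(float, sol.x)
            if b < 0:
                # (-b, c, -d) maps Z -> -Z, an identical distribution;
                # normalize to the increasing branch
                b, d = -b, -d
            return (-c, b, c, d)
    raise InfeasibleMomentsError(
        f"no polynomial solution at skewness {target_skew:g}, excess kurtosis "
        f"{target_excess_kurt:g} (family minimum about {boundary:.4f})"
    )


@dataclass(frozen=True)
class SyntheticSurveySpec:
    """Targets and nuisance settings for one generated survey.

    ``target_mean`` and ``target_sd`` describe the distribution *inside*
    ``target_window`` (default 4.0-18.0 g/dL): reference survey summaries
    are computed on plausibility-trimmed values, so the generator inflates
    the raw location/scale just enough that the trimmed population moments
    hit the targets. Set ``target_window=None`` to target the untrimmed
    distribution instead.
    """

    n: int
    target_mean: float
    target_sd: float
    target_skew: float = 0.0
    target_excess_kurt: float = 0.0
    target_window: tuple[float, float] | None = (4.0, 18.0)
    contamination_rate: float = 0.0
    contamination_low: tuple[float, float] = (1.0, 4.0)
    contamination_high: tuple[float, float] = (18.0, 25.6)
    rounding_step: float = 0.1
    seed: int = 0
    survey_id: str = "SYN-001"
    group: Group = Group.CHILD
    country: str = "C00"
    site: str = "S000"
    year: int = 2017

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")
        if not 0 <= self.contamination_rate <= 0.1:
            raise ValueError("contamination_rate must be in [0, 0.1]")


_GRID_Z = np.linspace(-8.0, 8.0, 4001)
_GRID_W = np.exp(-0.5 * _GRID_Z * _GRID_Z)
_GRID_W /= _GRID_W.sum()


def _trimmed_moments(
    coeffs: tuple[float, float, float, float],
    m: float,
    s: float,
    window: tuple[float, float],
) -> tuple[float, float, float, float, float]:
    """Population (mass, mean, SD, skew, excess kurtosis) of m + s*X
    restricted to ``window``, by quadrature over the Gaussian base."""
    a, b, c, d = coeffs
    y = m + s * (a + _GRID_Z * (b + _GRID_Z * (c + _GRID_Z * d)))
    mask = (y >= window[0]) & (y <= window[1])
    w, yk = _GRID_W[mask], y[mask]
    mass = float(w.sum())
    if mass <= 0:
        return 0.0, m, s, 0.0, 0.0
    mu = float(w @ yk) / mass
    dev = yk - mu
    m2 = float(w @ dev**2) / mass
    m3 = float(w @ dev**3) / mass
    m4 = float(w @ dev**4) / mass
    return mass, mu, math.sqrt(m2), m3 / m2**1.5, m4 / m2**2 - 3.0


def _window_matched_params(
    mean: float,
    sd: float,
    skew: float,
    ekurt: float,
    window: tuple[float, float],
) -> tuple[tuple[float, float, float, float], float, float]:
    """Polynomial coefficients and location/scale whose *trimmed* population
    moments match the four targets.

    Trimming to the plausibility window shrinks SD and pulls skewness and
    kurtosis toward normality (kurtosis especially: a 1e-4 tail mass at 5
    SD carries visible fourth-moment weight), so the raw family parameters
    are iterated until the trimmed moments hit the targets. Damped fixed
    point; shape targets are clamped to the feasible region, so extreme
    draws are matched as closely as the family allows (best effort).
    """
    sk_i, ku_i = skew, ekurt
    m, s = mean, sd
    coeffs = solve_moment_coefficients(sk_i, ku_i)
    for _ in range(40):
        mass, mu, sd_t, g1_t, g2_t = _trimmed_moments(coeffs, m, s, window)
        if mass < 0.5:  # window excludes most mass: give up cleanly
            return solve_moment_coefficients(skew, ekurt), mean, sd
        if (
            abs(mu - mean) < 1e-6
            and abs(sd_t - sd) < 1e-6
            and abs(g1_t - skew) < 1e-4
            and abs(g2_t - ekurt) < 1e-4
        ):
            break
        m += mean - mu
        s *= sd / sd_t
        sk_new = float(np.clip(sk_i + 0.8 * (skew - g1_t), -2.5, 2.5))
        ku_new = min(ku_i + 0.8 * (ekurt - g2_t), 20.0)
        ku_new = max(ku_new, feasibility_boundary(sk_new) + 0.01)
        if (sk_new, ku_new) != (sk_i, ku_i):
            sk_i, ku_i = sk_new, ku_new
            coeffs = solve_moment_coefficients(sk_i, ku_i)
    return coeffs, m, s


def generate_values(spec: SyntheticSurveySpec) -> np.ndarray:
    """Generate the survey's Hb values (g/dL) as an array.

    Pipeline: polynomial transform of standard normals -> location/scale to
    (mean, SD) -> gross-error contamination (each record independently
    replaced with probability ``contamination_rate`` by a uniform draw from
    the low or high implausible range, chosen with equal probability) ->
    rounding to the display step -> clipping to the device range.
    """
    if spec.target_window is not None:
        coeffs, m, s = _window_matched_params(
            spec.target_mean, spec.target_sd, spec.target_skew,
            spec.target_excess_kurt, spec.target_window,
        )
    else:
        coeffs = solve_moment_coefficients(spec.target_skew,
                                           spec.target_excess_kurt)
        m, s = spec.target_mean, spec.target_sd
    a, b, c, d = coeffs
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(spec.n)
    x = a + z * (b + z * (c + z * d))
    values = m + s * x
    if spec.contamination_rate > 0:
        contaminate = rng.random(spec.n) < spec.contamination_rate
        n_bad = int(contaminate.sum())
        if n_bad:
            side_high = rng.random(n_bad) < 0.5
            lo = rng.uniform(*spec.contamination_low, size=n_bad)
            hi = rng.uniform(*spec.contamination_high, size=n_bad)
            values[contaminate] = np.where(side_high, hi, lo)
    if spec.rounding_step > 0:
        values = np.round(values / spec.rounding_step) * spec.rounding_step
    return np.clip(values, *_CLIP)


def generate_survey(spec: SyntheticSurveySpec) -> Survey:
    """Generate a fully populated :class:`Survey` (reproducible from seed)."""
    values = generate_values(spec)
    records = [
        HbRecord(
            record_id=f"{spec.survey_id}-{spec.group.value}-{i:06d}",
            survey_id=spec.survey_id,
            group=spec.group,
            hb_gdl=float(v),
            pregnant=False if spec.group is Group.WRA else None,
            altitude_adjusted=True,
            country=spec.country,
            site=spec.site,
            year=spec.year,
            valid=True,
        )
        for i, v in enumerate(values)
    ]
    return Survey(
        survey_id=spec.survey_id, group=spec.group, records=records,
        country=spec.country, site=spec.site, year=spec.year,
    )


@dataclass(frozen=True)
class GroupHyper:
    """Hyper-distribution of per-survey targets for one demographic group.

    Each (mu, sigma) pair parameterizes a normal hyper-distribution from
    which a survey's target statistic is drawn. Defaults emulate the
    across-survey mean/SD of the reference child corpus.
    """

    mean: tuple[float, float] = (11.1, 0.50)
    sd: tuple[float, float] = (1.39, 0.21)
    skew: tuple[float, float] = (-0.37, 0.26)
    excess_kurt: tuple[float, float] = (0.54, 0.67)
    n_range: tuple[int, int] = (175, 649)
    contamination_rate: float = 0.0008


#: WRA hyper-parameters of the emulated corpus.
WRA_HYPER = GroupHyper(
    mean=(12.6, 0.57), sd=(1.47, 0.23), skew=(-0.53, 0.36),
    excess_kurt=(1.15, 1.17), n_range=(99, 406), contamination_rate=0.0014,
)


@dataclass(frozen=True)
class CorpusSpec:
    """A multi-site corpus: one child and one WRA survey per site.

    ``mean_sd_coupling`` is the Gaussian-copula correlation between a
    survey's target mean and target SD (negative: anemic populations show
    wider Hb distributions); ``cross_group_sd_corr`` correlates the child
    and WRA SD targets of the same site.
    """

    n_surveys: int = 400
    child: GroupHyper = field(default_factory=GroupHyper)
    wra: GroupHyper = field(default_factory=lambda: WRA_HYPER)
    mean_sd_coupling: float = -0.33
    cross_group_sd_corr: float = 0.52
    n_countries: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surveys < 1:
            raise ValueError("n_surveys must be >= 1")
        for r in (self.mean_sd_coupling, self.cross_group_sd_corr):
            if not -1 < r < 1:
                raise ValueError("correlations must lie in (-1, 1)")

    def to_dict(self) -> dict:
        def gh(g: GroupHyper) -> dict:
            return {
                "mean": list(g.mean), "sd": list(g.sd), "skew": list(g.skew),
                "excess_kurt": list(g.excess_kurt),
                "n_range": list(g.n_range),
                "contamination_rate": g.contamination_rate,
            }

        return {
            "n_surveys": self.n_surveys,
            "child": gh(self.child), "wra": gh(self.wra),
            "mean_sd_coupling": self.mean_sd_coupling,
            "cross_group_sd_corr": self.cross_group_sd_corr,
            "n_countries": self.n_countries,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorpusSpec":
        def gh(sub: dict, base: GroupHyper) -> GroupHyper:
            kwargs = {}
            for key in ("mean", "sd", "skew", "excess_kurt", "n_range"):
                if key in sub:
                    tp = int if key == "n_range" else float
                    kwargs[key] = tuple(map(tp, sub[key]))
            if "contamination_rate" in sub:
                kwargs["contamination_rate"] = float(sub["contamination_rate"])
            return GroupHyper(**{**base.__dict__, **kwargs}) if kwargs else base

        kwargs: dict = {}
        for key in ("n_surveys", "n_countries", "seed"):
            if key in d:
                kwargs[key] = int(d[key])
        for key in ("mean_sd_coupling", "cross_group_sd_corr"):
            if key in d:
                kwargs[key] = float(d[key])
        if "child" in d:
            kwargs["child"] = gh(d["child"], GroupHyper())
        if "wra" in d:
            kwargs["wra"] = gh(d["wra"], WRA_HYPER)
        return cls(**kwargs)


def _target_correlation(spec: CorpusSpec) -> np.ndarray:
    """Correlation of (child mean, child SD, WRA mean, WRA SD) z-scores."""
    r, s = spec.mean_sd_coupling, spec.cross_group_sd_corr
    corr = np.array([
        [1.0, r, 0.0, 0.0],
        [r, 1.0, 0.0, s],
        [0.0, 0.0, 1.0, r],
        [0.0, s, r, 1.0],
    ])
    # validate positive definiteness before use
    if np.min(np.linalg.eigvalsh(corr)) <= 1e-10:
        raise ValueError(
            "mean_sd_coupling and cross_group_sd_corr jointly inconsistent "
            "(target correlation matrix not positive definite)"
        )
    return corr


def _clamped_shape(rng: np.random.Generator, hyper: GroupHyper) -> tuple[float, float]:
    """Draw (skew, excess kurtosis) targets, kept inside the feasible region."""
    skew = float(np.clip(rng.normal(*hyper.skew), -2.0, 2.0))
    kurt = float(np.clip(rng.normal(*hyper.excess_kurt), -10.0, 10.0))
    kurt = max(kurt, feasibility_boundary(skew) + 0.05)
    return skew, kurt


def generate_corpus(spec: CorpusSpec) -> list[Survey]:
    """Generate the paired corpus: per site, one child and one WRA survey.

    Per-survey targets are drawn from the group hyper-distributions through
    a Gaussian copula carrying the mean-SD coupling and the cross-group SD
    correlation; per-survey seeds derive deterministically from the master
    seed. Returns surveys ordered site by site (child first).
    """
    master = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(_target_correlation(spec))
    surveys: list[Survey] = []
    for i in range(spec.n_surveys):
        z = chol @ master.standard_normal(4)
        cm = spec.child.mean[0] + spec.child.mean[1] * z[0]
        cs = max(0.3, spec.child.sd[0] + spec.child.sd[1] * z[1])
        wm = spec.wra.mean[0] + spec.wra.mean[1] * z[2]
        ws = max(0.3, spec.wra.sd[0] + spec.wra.sd[1] * z[3])
        site = f"S{i:04d}"
        country = f"C{i % spec.n_countries:02d}"
        year = _YEARS[i % len(_YEARS)]
        for group, hyper, mean, sd in (
            (Group.CHILD, spec.child, cm, cs),
            (Group.WRA, spec.wra, wm, ws),
        ):
            skew, kurt = _clamped_shape(master, hyper)
            n = int(master.integers(hyper.n_range[0], hyper.n_range[1] + 1))
            seed = int(master.integers(0, 2**31 - 1))
            surveys.append(
                generate_survey(
                    SyntheticSurveySpec(
                        n=n, target_mean=mean, target_sd=sd, target_skew=skew,
                        target_excess_kurt=kurt,
                        contamination_rate=hyper.contamination_rate,
                        seed=seed, survey_id=f"SVY-{i:04d}", group=group,
                        country=country, site=site, year=year,
                    )
                )
            )
    return surveys


def write_corpus_csv(surveys: Sequence[Survey], path) -> None:
    """Write surveys in the CSV schema the ingestion module reads."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "record_id", "survey_id", "country", "site", "year", "group",
            "pregnant", "hb_gdl", "altitude_m", "altitude_adjusted",
        ])
        for survey in surveys:
            for r in survey.records:
                writer.writerow([
                    r.record_id, r.survey_id, r.country, r.site,
                    r.year if r.year is not None else "",
                    r.group.value,
                    "" if r.pregnant is None else str(r.pregnant).lower(),
                    "" if r.hb_gdl is None else f"{r.hb_gdl:.1f}",
                    "" if r.altitude_m is None else f"{r.altitude_m:g}",
                    str(r.altitude_adjusted).lower(),
                ])
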