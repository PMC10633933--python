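"""Moment-matching solver and the synthetic survey/corpus generators."""

import math

import numpy as np
import pytest
import sympy

from hbqc import (
    CorpusSpec,
    Group,
    GroupHyper,
    InfeasibleMomentsError,
    SyntheticSurveySpec,
    feasibility_boundary,
    generate_corpus,
    generate_survey,
    generate_values,
    solve_moment_coefficients,
    summarize_survey,
    write_corpus_csv,
)
from hbqc.distribution_stats import kurtosis_g2, sample_sd, skewness_g1
from hbqc.survey_model import read_surveys


def _population_moments(a, b, c, d):
    """Independent oracle: exact moments of X = a + bZ + cZ^2 + dZ^3 via
    symbolic expansion against Gaussian raw moments E[Z^k]."""
    z = sympy.Symbol("z")
    x = a + b * z + c * z**2 + d * z**3

    def E(expr):
        poly = sympy.Poly(sympy.expand(expr), z)
        total = sympy.Integer(0)
        for (k,), coef in poly.terms():
            if k % 2 == 0:
                total += coef * sympy.factorial2(k - 1) if k else coef
        return total

    mean = E(x)
    var = E((x - mean) ** 2)
    skew = E((x - mean) ** 3) / var ** sympy.Rational(3, 2)
    ekurt = E((x - mean) ** 4) / var**2 - 3
    return (float(mean), float(var), float(skew), float(ekurt))


class TestMomentSolver:
    def test_normal_targets_identity(self):
        assert solve_moment_coefficients(0.0, 0.0) == (0.0, 1.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "skew,ekurt",
        [(-0.53, 1.15), (-0.37, 0.54), (0.8, 1.0), (0.0, 2.5), (-1.3, 3.0)],
    )
    def test_solution_moments_match_targets(self, skew, ekurt):
        a, b, c, d = solve_moment_coefficients(skew, ekurt)
        mean, var, got_skew, got_ekurt = _population_moments(
            sympy.Float(a, 30), sympy.Float(b, 30), sympy.Float(c, 30),
            sympy.Float(d, 30)
        )
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert var == pytest.approx(1.0, abs=1e-9)
        assert got_skew == pytest.approx(skew, abs=1e-9)
        assert got_ekurt == pytest.approx(ekurt, abs=1e-9)

    def test_infeasible_targets_raise_with_boundary(self):
        with pytest.raises(InfeasibleMomentsError, match="minimum"):
            solve_moment_coefficients(2.0, -1.0)
        with pytest.raises(InfeasibleMomentsError):
            solve_moment_coefficients(0.0, -1.16)

    def test_boundary_curve_shape(self):
        assert feasibility_boundary(0.0) == pytest.approx(-1.1513)
        assert feasibility_boundary(1.0) > feasibility_boundary(0.0)
        assert feasibility_boundary(-0.5) == feasibility_boundary(0.5)


class TestGenerateSurvey:
    def test_determinism_identical_records(self):
        spec = SyntheticSurveySpec(n=500, target_mean=11.1, target_sd=1.39,
                                   target_skew=-0.37, target_excess_kurt=0.54,
                                   seed=99)
        assert generate_survey(spec).records == generate_survey(spec).records

    def test_different_seeds_differ(self):
        base = dict(n=500, target_mean=11.1, target_sd=1.39)
        a = generate_values(SyntheticSurveySpec(**base, seed=1))
        b = generate_values(SyntheticSurveySpec(**base, seed=2))
        assert not np.array_equal(a, b)

    def test_moment_recovery_improves_with_n(self):
        targets = (11.1, 1.39, -0.37, 0.54)
        errs = {}
        for n in (400, 10_000, 1_000_000):
            spec = SyntheticSurveySpec(
                n=n, target_mean=targets[0], target_sd=targets[1],
                target_skew=targets[2], target_excess_kurt=targets[3], seed=3,
            )
            v = generate_values(spec)
            v = v[(v >= 4.0) & (v <= 18.0)]  # targets describe this window
            errs[n] = (
                abs(v.mean() - targets[0]),
                abs(sample_sd(v) - targets[1]),
                abs(skewness_g1(v) - targets[2]),
                abs(kurtosis_g2(v) - targets[3]),
            )
        assert errs[1_000_000][0] < 0.01 and errs[1_000_000][1] < 0.01
        assert errs[1_000_000][2] < 0.02 and errs[1_000_000][3] < 0.05
        # bias shrinks from field-survey n to the large-n limit
        assert all(big <= small for big, small in zip(errs[1_000_000],
                                                      errs[400]))

    def test_contamination_rate_recovered(self):
        spec = SyntheticSurveySpec(
            n=100_000, target_mean=11.1, target_sd=1.39, target_skew=-0.37,
            target_excess_kurt=0.54, contamination_rate=0.01, seed=17,
        )
        v = generate_values(spec)
        frac = np.mean((v < 4.0) | (v > 18.0))
        se = math.sqrt(0.01 * 0.99 / spec.n)
        assert abs(frac - 0.01) < 3 * se

    def test_contamination_off_negligible_tail_mass(self):
        spec = SyntheticSurveySpec(
            n=100_000, target_mean=11.1, target_sd=1.39, target_skew=-0.37,
            target_excess_kurt=0.54, seed=23,
        )
        survey = generate_survey(spec)
        stats = summarize_survey(survey)
        assert stats.flag_pct < 0.5

    def test_values_respect_device_range_and_step(self):
        spec = SyntheticSurveySpec(n=5000, target_mean=11.1, target_sd=1.39,
                                   seed=4)
        v = generate_values(spec)
        assert v.min() >= 0.0 and v.max() <= 25.6
        assert np.allclose(np.round(v / 0.1) * 0.1, v, atol=1e-9)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticSurveySpec(n=0, target_mean=11.0, target_sd=1.0)
        with pytest.raises(ValueError):
            SyntheticSurveySpec(n=10, target_mean=11.0, target_sd=-1.0)
        with pytest.raises(ValueError):
            SyntheticSurveySpec(n=10, target_mean=11.0, target_sd=1.0,
                                contamination_rate=0.5)


class TestGenerateCorpus:
    def test_paired_structure(self, small_corpus):
        sites = {}
        for s in small_corpus:
            sites.setdefault(s.survey_id, set()).add(s.group)
        assert all(groups == {Group.CHILD, Group.WRA}
                   for groups in sites.values())

    def test_determinism(self):
        spec = CorpusSpec(n_surveys=5, seed=42)
        a = generate_corpus(spec)
        b = generate_corpus(spec)
        assert [s.valid_values().tolist() for s in a] == [
            s.valid_values().tolist() for s in b
        ]

    def test_zero_hyper_sd_shares_targets(self):
        hyper = GroupHyper(mean=(11.1, 0.0), sd=(1.39, 0.0), skew=(-0.37, 0.0),
                           excess_kurt=(0.54, 0.0), n_range=(2000, 2000),
                           contamination_rate=0.0)
        corpus = generate_corpus(CorpusSpec(n_surveys=6, child=hyper,
                                            wra=hyper, seed=8))
        stats = [summarize_survey(s) for s in corpus]
        means = [s.mean_gdl for s in stats]
        # all surveys target the same moments; spread is sampling noise only
        assert np.std(means) < 3 * 1.39 / math.sqrt(2000)

    def test_inverse_coupling_yields_negative_mean_sd_rho(self):
        from hbqc import mean_sd_correlation

        spec = CorpusSpec(n_surveys=60, mean_sd_coupling=-0.9,
                          cross_group_sd_corr=0.0, seed=13)
        stats = [summarize_survey(s) for s in generate_corpus(spec)]
        child = [s for s in stats if s.group is Group.CHILD]
        rho, _ = mean_sd_correlation(child)
        assert rho < -0.5

    def test_csv_round_trip(self, tmp_path, small_corpus):
        subset = small_corpus[:4]
        path = tmp_path / "corpus.csv"
        write_corpus_csv(subset, path)
        surveys = read_surveys(path)
        by_key = {(s.survey_id, s.group): s for s in surveys}
        for original in subset:
            loaded = by_key[(original.survey_id, original.group)]
            assert np.allclose(loaded.valid_values(),
                               original.valid_values(), atol=1e-9)
            assert loaded.country == original.country
            assert loaded.year == original.year

    def test_byte_identical_csv_for_same_seed(self, tmp_path):
        spec = CorpusSpec(n_surveys=3, seed=77)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_corpus_csv(generate_corpus(spec), p1)
        write_corpus_csv(generate_corpus(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_inconsistent_correlations_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            generate_corpus(CorpusSpec(n_surveys=2, mean_sd_coupling=-0.95,
                                       cross_group_sd_corr=0.95, seed=1))
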