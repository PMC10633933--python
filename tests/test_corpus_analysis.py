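"""Corpus percentile tables, correlations, and paired comparisons."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from hbqc import (
    Group,
    mean_sd_correlation,
    paired_compare,
    paired_statistic_correlation,
    spearman_rho,
    stats_to_frame,
    summarize_corpus,
)

from conftest import make_stats


def _brute_spearman(x, y):
    """Independent mid-rank oracle: Pearson correlation of mid-ranks."""

    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSummarizeCorpus:
    def test_three_survey_arithmetic(self):
        stats = [make_stats(survey_id=f"S{i}", sd=sd)
                 for i, sd in enumerate([1.2, 1.3, 1.4])]
        table = summarize_corpus(stats, Group.CHILD).table
        assert table.loc["mean", "sd"] == pytest.approx(1.3)
        assert table.loc["min", "sd"] == pytest.approx(1.2)
        assert table.loc["max", "sd"] == pytest.approx(1.4)

    def test_vacuous_filter_identical(self, small_corpus_stats):
        base = summarize_corpus(small_corpus_stats, Group.CHILD)
        filtered = summarize_corpus(
            small_corpus_stats, Group.CHILD, lambda s: s.country == "NOWHERE"
        )
        assert base.table.equals(filtered.table)

    def test_quantile_rows_monotone(self, small_corpus_stats):
        for group in (Group.CHILD, Group.WRA):
            table = summarize_corpus(small_corpus_stats, group).table
            ladder = ["min", "p2.5", "p10", "p25", "p50", "p75", "p90",
                      "p97.5", "max"]
            for stat in table.columns:
                values = table.loc[ladder, stat].to_numpy(dtype=float)
                assert np.all(np.diff(values) >= -1e-12), stat

    def test_too_few_surveys_names_filter(self):
        stats = [make_stats(survey_id="S0")]
        with pytest.raises(ValueError, match="one-country"):
            summarize_corpus(stats, Group.CHILD, label="one-country")


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        rho, _ = spearman_rho(x, [2.0, 3.0, 7.0, 11.0])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho(x, [-1.0, -2.0, -3.0, -4.0])
        assert rho == pytest.approx(-1.0)

    def test_tied_fixture_matches_midrank_oracle(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(_brute_spearman(x, y), abs=1e-12)

    def test_random_ties_match_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(_brute_spearman(x, y), abs=1e-12)

    def test_bounds_symmetry_and_monotone_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        rho_xy, _ = spearman_rho(x, y)
        rho_yx, _ = spearman_rho(y, x)
        assert -1 <= rho_xy <= 1 and rho_xy == pytest.approx(rho_yx)
        rho_t, _ = spearman_rho(np.exp(x), y)  # strictly monotone transform
        assert rho_t == pytest.approx(rho_xy, abs=1e-12)

    def test_constant_vector_unavailable(self):
        rho, p = spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho) and math.isnan(p)


class TestPairedCompare:
    def _pairs(self, child_vals, wra_vals):
        child = [make_stats(survey_id=f"S{i}", sd=v)
                 for i, v in enumerate(child_vals)]
        wra = [make_stats(survey_id=f"S{i}", group=Group.WRA, sd=v)
               for i, v in enumerate(wra_vals)]
        return child, wra

    def test_identical_vectors(self):
        child, wra = self._pairs([1.3, 1.4, 1.5], [1.3, 1.4, 1.5])
        cmp = paired_compare(child, wra, "sd")
        assert cmp.difference == 0.0 and cmp.ci95 == (0.0, 0.0)

    def test_constant_shift_degenerate_ci(self):
        child, wra = self._pairs([1.3, 1.4, 1.5], [1.4, 1.5, 1.6])
        cmp = paired_compare(child, wra, "sd")
        assert cmp.difference == pytest.approx(-0.1)
        assert cmp.ci95[0] == pytest.approx(-0.1, abs=1e-9)
        assert cmp.ci95[1] == pytest.approx(-0.1, abs=1e-9)
        assert math.isnan(cmp.p_value)

    def test_sign_convention_child_minus_wra(self, rng):
        """With WRA SDs generated above child SDs, the difference is negative."""
        child_sd = rng.normal(1.39, 0.05, size=60)
        wra_sd = child_sd + 0.08 + rng.normal(0, 0.02, size=60)
        child, wra = self._pairs(child_sd, wra_sd)
        cmp = paired_compare(child, wra, "sd")
        assert cmp.difference < 0
        assert cmp.ci95[0] <= cmp.difference <= cmp.ci95[1]
        assert cmp.difference == pytest.approx(cmp.mean_child - cmp.mean_wra)

    def test_ci_coverage_of_true_gap(self, rng):
        """95% t interval covers a true paired gap of -0.07 in >= 90% of
        500 seeded replicates (30 pairs each)."""
        gap, hits = -0.07, 0
        for _ in range(500):
            base = rng.normal(1.4, 0.15, size=30)
            child, wra = self._pairs(
                base + rng.normal(0, 0.05, 30),
                base - gap + rng.normal(0, 0.05, 30),
            )
            lo, hi = paired_compare(child, wra, "sd").ci95
            hits += lo <= gap <= hi
        assert hits >= 450

    def test_wilcoxon_alternative(self, rng):
        child, wra = self._pairs(rng.normal(1.39, 0.1, 40),
                                 rng.normal(1.47, 0.1, 40))
        cmp = paired_compare(child, wra, "sd", method="wilcoxon")
        assert cmp.method == "wilcoxon"
        d = np.array([c.sd_gdl for c in child]) - np.array(
            [w.sd_gdl for w in wra])
        assert cmp.p_value == pytest.approx(float(sps.wilcoxon(d).pvalue))

    def test_no_pairs_raises(self):
        child = [make_stats(survey_id="A")]
        wra = [make_stats(survey_id="B", group=Group.WRA)]
        with pytest.raises(ValueError, match="no matched"):
            paired_compare(child, wra, "sd")


class TestMeanSDCorrelation:
    def test_perfect_inverse_ranking(self):
        stats = [make_stats(survey_id=f"S{i}", mean=10 + i, sd=2.0 - 0.1 * i)
                 for i in range(10)]
        rho, _ = mean_sd_correlation(stats)
        assert rho == pytest.approx(-1.0)

    def test_independent_null(self, rng):
        stats = [
            make_stats(survey_id=f"S{i}", mean=rng.normal(11, 0.5),
                       sd=rng.normal(1.4, 0.2))
            for i in range(300)
        ]
        rho, p = mean_sd_correlation(stats)
        assert abs(rho) < 0.15 and p > 0.01

    def test_coupled_generator_negative(self, small_corpus_stats):
        """The corpus generator's built-in mean-SD coupling shows up as a
        negative rank correlation."""
        child = [s for s in small_corpus_stats if s.group is Group.CHILD]
        rho, _ = mean_sd_correlation(child)
        assert rho < 0

    def test_cross_group_sd_correlation_positive(self, small_corpus_stats):
        child = [s for s in small_corpus_stats if s.group is Group.CHILD]
        wra = [s for s in small_corpus_stats if s.group is Group.WRA]
        rho, _ = paired_statistic_correlation(child, wra, "sd")
        assert rho > 0


def test_stats_frame_column_order(small_corpus_stats):
    frame = stats_to_frame(small_corpus_stats)
    assert list(frame.columns[:10]) == [
        "survey_id", "group", "n", "mean", "median", "sd",
        "skewness_g1", "kurtosis_g2", "anemia_pct", "flag_pct",
    ]
    assert len(frame) == len(small_corpus_stats)
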