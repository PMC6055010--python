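"""Hypothesis tests and group summaries.

Frozen expected values were computed with R 4.3 (t.test, wilcox.test, aov +
TukeyHSD, kruskal.test) as an independent oracle.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmapkit import (
    DegenerateDataError,
    GroupSummary,
    TwoGroupTable,
    format_report,
    one_way_anova,
    results_to_json,
    summarize_groups,
    summary_t_test,
    two_sample_test,
)


def _table(a, b, names=("a", "b")):
    return TwoGroupTable(names, (np.asarray(a, float), np.asarray(b, float)))


class TestTwoSample:
    def test_identical_groups_p_one(self):
        r = two_sample_test(_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_student_textbook_example(self):
        # R: t.test(c(1,2,3), c(4,5,6), var.equal=TRUE)
        r = two_sample_test(_table([1, 2, 3], [4, 5, 6]), method="student")
        assert r.statistic == pytest.approx(-3.67423461417477, abs=1e-10)
        assert r.df == 4
        assert r.p_value == pytest.approx(0.0213116411287567, abs=1e-10)

    def test_mann_whitney_exact_matches_r(self):
        # R: wilcox.test(a, b, exact=TRUE) -> U = 8, p = 0.7301587...
        r = two_sample_test(
            _table([1.1, 2.3, 3.1, 4.2, 5.9], [2.2, 3.4, 4.1, 6.3]),
            method="mann_whitney",
        )
        assert r.statistic == 8.0
        assert r.p_value == pytest.approx(0.730158730159, abs=1e-9)
        assert r.extras["mode"] == "exact"

    def test_mann_whitney_ties_fall_back_to_asymptotic(self):
        r = two_sample_test(
            _table([1.0, 1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 4.0]), method="mann_whitney"
        )
        assert r.extras["mode"] == "asymptotic"

    def test_zero_variance_equal_means_convention(self):
        r = two_sample_test(_table([2.0, 2.0], [2.0, 2.0]))
        assert r.p_value == 1.0
        assert "degenerate" in r.extras

    def test_zero_variance_unequal_means_error(self):
        with pytest.raises(DegenerateDataError):
            two_sample_test(_table([2.0, 2.0], [3.0, 3.0]))

    def test_t_test_needs_two_per_group(self):
        with pytest.raises(DegenerateDataError):
            two_sample_test(_table([1.0], [2.0, 3.0]), method="welch")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           method=st.sampled_from(["student", "welch", "mann_whitney"]))
    def test_p_invariant_to_group_order(self, seed, method):
        gen = np.random.default_rng(seed)
        table = _table(gen.normal(0, 1, 6), gen.normal(0.5, 2, 8))
        r1 = two_sample_test(table, method=method)
        r2 = two_sample_test(table.swapped(), method=method)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)


class TestSummaryTTest:
    def test_equal_summaries_give_p_one(self):
        s = GroupSummary("a", 6, 4.0, 1.0)
        r = summary_t_test(s, GroupSummary("b", 6, 4.0, 1.0))
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_equivalent_to_raw_test_on_moment_matched_data(self, rng):
        """Any raw samples with exactly the summarized moments give the same t."""
        for method in ("student", "welch"):
            raw = [rng.normal(size=6), rng.normal(size=8)]
            std = [
                (x - x.mean()) / x.std(ddof=1) * sd + mean
                for x, (mean, sd) in zip(raw, [(4.12, 2.13), (5.02, 1.43)])
            ]
            r_raw = two_sample_test(_table(*std), method=method)
            r_sum = summary_t_test(
                GroupSummary("a", 6, 4.12, 2.13),
                GroupSummary("b", 8, 5.02, 1.43),
                method=method,
            )
            assert r_raw.statistic == pytest.approx(r_sum.statistic, abs=1e-12)
            assert r_raw.p_value == pytest.approx(r_sum.p_value, abs=1e-12)
            assert r_raw.df == pytest.approx(r_sum.df, abs=1e-9)

    def test_doubling_sds_halves_t(self):
        a, b = GroupSummary("a", 6, 4.0, 1.0), GroupSummary("b", 6, 5.0, 1.5)
        t1 = summary_t_test(a, b, "student").statistic
        a2, b2 = GroupSummary("a", 6, 4.0, 2.0), GroupSummary("b", 6, 5.0, 3.0)
        t2 = summary_t_test(a2, b2, "student").statistic
        assert abs(t1) == pytest.approx(2 * abs(t2), rel=1e-12)

    def test_group_order_flips_sign_only(self):
        a, b = GroupSummary("a", 6, 4.12, 2.13), GroupSummary("b", 6, 5.02, 1.43)
        r1, r2 = summary_t_test(a, b), summary_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


ANOVA_X = {
    "g1": [1.2, 1.9, 2.4, 1.7, 2.1],
    "g2": [1.4, 2.2, 2.0, 1.8, 2.5],
    "g3": [4.6, 5.1, 4.4, 5.3, 4.9],
}


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        r = one_way_anova({"a": g, "b": g, "c": g})
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert all(row["p"] > 0.999 for row in r.extras["posthoc"])

    def test_shifted_group_flagged_matches_r(self):
        # R: aov -> F = 85.1811023622, p = 8.11855e-08;
        # TukeyHSD p: (g2-g1) 0.8904551, (g3-g1) 2e-07, (g3-g2) 3e-07
        r = one_way_anova(ANOVA_X, method="anova_tukey")
        assert r.statistic == pytest.approx(85.1811023622, rel=1e-9)
        assert r.p_value == pytest.approx(8.11855003662e-08, rel=1e-6)
        p = {(row["group_a"], row["group_b"]): row["p"] for row in r.extras["posthoc"]}
        assert p[("g1", "g2")] == pytest.approx(0.8904551, abs=1e-4)
        assert p[("g1", "g3")] < 1e-5
        assert p[("g2", "g3")] < 1e-5

    def test_kruskal_matches_r(self):
        # R: kruskal.test -> H = 9.5, p = 0.00865169520312
        r = one_way_anova(ANOVA_X, method="kruskal_posthoc")
        assert r.statistic == pytest.approx(9.5, rel=1e-9)
        assert r.p_value == pytest.approx(0.00865169520312, rel=1e-9)
        p = {(row["group_a"], row["group_b"]): row["p"] for row in r.extras["posthoc"]}
        assert p[("g1", "g2")] > 0.05
        assert p[("g1", "g3")] < 0.05 and p[("g2", "g3")] < 0.05

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="two_sample_test"):
            one_way_anova({"a": [1.0, 2.0], "b": [3.0, 4.0]})

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_holm_adjusted_p_monotone(self, seed):
        gen = np.random.default_rng(seed)
        groups = {f"g{i}": gen.normal(i * 0.3, 1, 6) for i in range(4)}
        r = one_way_anova(groups, method="kruskal_posthoc")
        adj = np.array([row["p"] for row in r.extras["posthoc"]])
        assert np.all(np.diff(np.sort(adj)) >= -1e-12)
        assert np.all((adj >= 0) & (adj <= 1))


class TestSummaries:
    def test_repeated_value_zero_sd(self):
        (s,) = summarize_groups({"rat": [4.12, 4.12]})
        assert (s.n, s.mean, s.sd) == (2, 4.12, 0.0)

    def test_single_value_rejected(self):
        with pytest.raises(DegenerateDataError):
            summarize_groups({"rat": [4.12]})

    def test_sample_sd_uses_n_minus_one(self, rng):
        x = rng.normal(size=9)
        (s,) = summarize_groups({"g": x})
        assert s.sd == pytest.approx(np.std(x, ddof=1))

    def test_report_renders_all_sections(self):
        sections = [
            (
                "amplitude_mV",
                [GroupSummary("rat", 6, 4.12, 2.13), GroupSummary("mouse", 6, 5.02, 1.43)],
                summary_t_test(
                    GroupSummary("rat", 6, 4.12, 2.13), GroupSummary("mouse", 6, 5.02, 1.43)
                ),
            )
        ]
        txt = format_report(sections)
        assert "amplitude_mV" in txt and "rat: n = 6, mean = 4.12" in txt
        assert "student" in txt
        js = results_to_json(sections)
        assert '"p_value"' in js
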