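"""Unit and property tests for assay scoring and inference."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from nemavoid.behavior import (
    BackingTimeRecord,
    ChemotaxisPlate,
    HeadResponseRecord,
    PowerSpec,
    chemotaxis_index,
    cohens_d,
    head_response_proportion,
    hochberg_adjust,
    one_way_anova_tukey,
    power_t_test,
    response_index_normalized,
    response_index_wildtype,
    run_figure_analysis,
    sample_size_t,
    sample_size_two_prop,
    significance_code,
    two_sample_t_test,
    two_sample_z_test,
)


def make_records(times, genotype="wt", treatment="SDS", day="day1"):
    return [
        BackingTimeRecord(f"{genotype}-{i}", genotype, treatment, day, t)
        for i, t in enumerate(times)
    ]


def hochberg_brute(p):
    """Closed-form oracle: adj(i) = min_{j >= i} (m - j) * p_(j), capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    adj_sorted = [
        min(1.0, min((m - j) * ps[j] for j in range(i, m))) for i in range(m)
    ]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Response indices
# ---------------------------------------------------------------------------

class TestResponseIndices:
    def test_sds_self_index_is_exactly_100(self):
        sds = make_records([1.5, 2.0, 2.5, 3.0])
        assert response_index_wildtype(sds, sds).index_percent == 100.0

    @pytest.mark.parametrize(
        "treat_times, sds_times, expected",
        [
            ([6.0, 6.0], [2.0, 2.0], 300.0),
            ([2.0, 2.0], [2.0, 2.0], 100.0),
            ([1.0], [4.0], 25.0),
        ],
    )
    def test_wildtype_index_arithmetic(self, treat_times, sds_times, expected):
        res = response_index_wildtype(
            make_records(treat_times, treatment="exp"), make_records(sds_times)
        )
        assert res.index_percent == pytest.approx(expected)
        assert res.normalization_mode == "wildtype_sds"

    def test_mutant_index_arithmetic(self):
        # mut: exp 8 s, buffer 10 s; wt: SDS 2 s, buffer 10 s -> (8/10)/(2/10) = 400%
        res = response_index_normalized(
            make_records([8.0, 8.0], "mut", "exp"),
            make_records([10.0, 10.0], "mut", "buffer"),
            make_records([2.0, 2.0], "wt", "SDS"),
            make_records([10.0, 10.0], "wt", "buffer"),
        )
        assert res.index_percent == pytest.approx(400.0)

    def test_mutant_equation_reduces_to_wildtype_when_buffers_match(self):
        rng = np.random.default_rng(7)
        treat = make_records(rng.gamma(4, 1.0, 30), "mut", "exp")
        sds = make_records(rng.gamma(2, 1.0, 30), "wt", "SDS")
        buffer = make_records(rng.gamma(9, 1.1, 30), "wt", "buffer")
        full = response_index_normalized(treat, buffer, sds, buffer)
        simple = response_index_wildtype(treat, sds)
        assert full.index_percent == pytest.approx(
            simple.index_percent, rel=1e-12
        )

    def test_wildtype_self_normalization_of_mutant_equation(self):
        sds = make_records([2.0, 2.2, 1.8], "wt", "SDS")
        buf = make_records([10.0, 9.0, 11.0], "wt", "buffer")
        res = response_index_normalized(sds, buf, sds, buf)
        assert res.index_percent == pytest.approx(100.0)

    def test_per_day_mode_uses_same_day_controls(self):
        # day1 index 50%, day2 index 200% -> equal-weight mean 125%
        treat = make_records([1.0], day="day1") + make_records([4.0], day="day2")
        sds = make_records([2.0], day="day1") + make_records([2.0], day="day2")
        res = response_index_wildtype(treat, sds, per_day=True)
        assert res.per_day == {"day1": 50.0, "day2": 200.0}
        assert res.index_percent == pytest.approx(125.0)

    def test_empty_group_and_missing_day_control_raise(self):
        sds = make_records([2.0])
        with pytest.raises(ValueError, match="empty"):
            response_index_wildtype([], sds)
        with pytest.raises(ValueError, match="same-day"):
            response_index_wildtype(
                make_records([1.0], day="day2"), sds, per_day=True
            )


# ---------------------------------------------------------------------------
# Proportions and chemotaxis
# ---------------------------------------------------------------------------

class TestProportionsAndChemotaxis:
    def test_head_response_proportion(self):
        recs = [
            HeadResponseRecord(str(i), "wt", "buffer", "day1", i < 8)
            for i in range(40)
        ]
        assert head_response_proportion(recs) == (0.2, 40)
        with pytest.raises(ValueError):
            head_response_proportion([])

    @pytest.mark.parametrize(
        "n_exp, n_ctrl, n_total, expected",
        [(50, 0, 50, 1.0), (20, 20, 50, 0.0), (30, 10, 50, 0.4), (0, 50, 50, -1.0)],
    )
    def test_chemotaxis_index(self, n_exp, n_ctrl, n_total, expected):
        plate = ChemotaxisPlate("p1", n_exp, n_ctrl, n_total)
        assert chemotaxis_index(plate) == pytest.approx(expected)

    @given(
        st.integers(0, 100), st.integers(0, 100), st.integers(0, 50)
    )
    def test_chemotaxis_index_bounded(self, n_exp, n_ctrl, extra):
        plate = ChemotaxisPlate("p", n_exp, n_ctrl, n_exp + n_ctrl + extra)
        if plate.n_total > 0:
            assert -1.0 <= chemotaxis_index(plate) <= 1.0

    def test_invalid_plate_counts_rejected(self):
        with pytest.raises(ValueError):
            ChemotaxisPlate("p", 30, 30, 50)
        with pytest.raises(ValueError):
            chemotaxis_index(ChemotaxisPlate("p", 0, 0, 0))


# ---------------------------------------------------------------------------
# z and t tests
# ---------------------------------------------------------------------------

class TestZTest:
    def test_pilot_proportions_example(self):
        # p1=0.8, p2=0.2, n=40 each: pooled pbar=0.5, SE=sqrt(0.25*0.05)
        res = two_sample_z_test(0.8, 40, 0.2, 40)
        assert res.statistic == pytest.approx(0.6 / math.sqrt(0.25 * 0.05))
        assert res.statistic == pytest.approx(5.367, abs=5e-4)

    def test_equal_proportions_give_zero_z(self):
        res = two_sample_z_test(0.5, 40, 0.5, 40)
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_antisymmetry_under_group_swap(self):
        a = two_sample_z_test(0.7, 30, 0.4, 50)
        b = two_sample_z_test(0.4, 50, 0.7, 30)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_raw == pytest.approx(b.p_raw)

    def test_degenerate_and_small_sample_behavior(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_sample_z_test(0.0, 40, 0.0, 40)
        with pytest.warns(UserWarning, match="expected cell count"):
            two_sample_z_test(0.1, 10, 0.5, 10)


class TestTTest:
    def test_hand_computed_example(self):
        # pooled sd = 1, SE = sqrt(2/3), t = -3/SE, df = 4
        res = two_sample_t_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3 / math.sqrt(2 / 3))
        assert res.statistic == pytest.approx(-3.674, abs=5e-4)
        assert res.p_raw == pytest.approx(0.0213, abs=5e-4)
        assert res.df == 4

    def test_identical_samples(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(1.0)

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        x, y = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        base = two_sample_t_test(x, y)
        scaled = two_sample_t_test([c * v for v in x], [c * v for v in y])
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_zero_variance_sentinels(self):
        equal = two_sample_t_test([2.0, 2.0], [2.0, 2.0])
        assert (equal.statistic, equal.p_raw) == (0.0, 1.0)
        apart = two_sample_t_test([1.0, 1.0], [2.0, 2.0])
        assert apart.statistic == -math.inf
        assert apart.p_raw == 0.0

    def test_agrees_with_scipy_pooled(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.7, 1.3, 17)
        mine = two_sample_t_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p_raw == pytest.approx(ref.pvalue, rel=1e-12)


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

class TestAnovaTukey:
    def test_forced_separation(self, rng):
        jitter = rng.normal(0, 1e-3, 4)
        groups = {
            "a": [0 + jitter[0], 0 + jitter[1]],
            "b": [0 + jitter[2], 0 + jitter[3]],
            "c": [10.0, 10.001],
        }
        results = one_way_anova_tukey(groups)
        overall = results[0]
        assert overall.statistic_name == "F"
        assert overall.p_raw < 1e-6
        by_pair = {r.comparison: r for r in results[1:]}
        assert by_pair[("a", "b")].p_adjusted > 0.05
        assert by_pair[("a", "c")].p_adjusted < 0.001
        assert by_pair[("b", "c")].p_adjusted < 0.001

    def test_identical_groups_yield_f_zero(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        results = one_way_anova_tukey(g)
        assert results[0].statistic == pytest.approx(0.0)
        assert all(r.p_adjusted == pytest.approx(1.0) for r in results[1:])

    def test_q_statistic_matches_studentized_range_p(self, rng):
        groups = {k: rng.normal(m, 1, 8) for k, m in zip("abc", (0, 0.5, 2))}
        results = one_way_anova_tukey(groups)
        for r in results[1:]:
            p_from_q = stats.studentized_range.sf(r.statistic, 3, r.df)
            assert r.p_adjusted == pytest.approx(p_from_q, abs=1e-8)

    def test_preconditions(self):
        with pytest.raises(ValueError, match=">= 3 groups"):
            one_way_anova_tukey({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(ValueError, match="< 2 observations"):
            one_way_anova_tukey({"a": [1, 2], "b": [3, 4], "c": [5]})


# ---------------------------------------------------------------------------
# Hochberg adjustment
# ---------------------------------------------------------------------------

class TestHochberg:
    def test_worked_example(self):
        assert hochberg_adjust([0.01, 0.04, 0.03]) == pytest.approx(
            [0.03, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert hochberg_adjust([0.37]) == [0.37]

    @given(st.lists(st.integers(0, 100), min_size=1, max_size=8))
    def test_matches_brute_force_and_dominates_raw(self, grid):
        p = [v / 100 for v in grid]
        adj = np.array(hochberg_adjust(p))
        assert np.allclose(adj, hochberg_brute(p), atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        for _ in range(200):
            p = rng.random(rng.integers(1, 7))
            assert np.allclose(
                hochberg_adjust(p), sm.multipletests(p, method="simes-hochberg")[1]
            )

    def test_order_statistics_monotone(self, rng):
        p = rng.random(10)
        adj = np.array(hochberg_adjust(p))
        assert np.all(np.diff(np.sort(adj)) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            hochberg_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# Effect size, power, sample size
# ---------------------------------------------------------------------------

class TestEffectAndPower:
    def test_cohens_d_arithmetic(self):
        # means 10 and 5, both sds 2.5 -> d = 2.0
        x = [7.5, 10.0, 12.5]
        y = [2.5, 5.0, 7.5]
        assert cohens_d(x, y) == pytest.approx(2.0)
        assert cohens_d(y, x) == pytest.approx(-2.0)

    def test_cohens_d_translation_invariance(self, rng):
        x = rng.normal(3, 1, 20)
        y = rng.normal(1, 1, 25)
        assert cohens_d(x + 100, y + 100) == pytest.approx(cohens_d(x, y))

    def test_cohens_d_zero_cases(self):
        assert cohens_d([1.0, 2.0], [1.0, 2.0]) == 0.0
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [2.0, 2.0])

    def test_sample_size_t_large_effect(self):
        assert sample_size_t(PowerSpec(cohens_d=0.8)) == 26
        assert power_t_test(26, 0.8) >= 0.8
        assert power_t_test(25, 0.8) < 0.8

    def test_sample_size_t_high_power(self):
        # noncentral-t solve verified against statsmodels (58.39 -> 59)
        n = sample_size_t(PowerSpec(cohens_d=0.8, power=0.99))
        assert n == 59
        assert power_t_test(n, 0.8) >= 0.99 > power_t_test(n - 1, 0.8)

    def test_sample_size_monotone_in_effect(self):
        n_small = sample_size_t(PowerSpec(cohens_d=0.8))
        n_large = sample_size_t(PowerSpec(cohens_d=1.6))
        assert n_large < n_small

    def test_power_matches_statsmodels(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        ref = smp.TTestIndPower()
        for n, d in ((10, 0.5), (26, 0.8), (40, 1.2)):
            assert power_t_test(n, d) == pytest.approx(
                ref.power(effect_size=d, nobs1=n, alpha=0.05), rel=1e-9
            )

    def test_two_prop_pilot_calculation(self):
        h, n = sample_size_two_prop(PowerSpec(proportions=(0.3, 0.8)))
        assert h == pytest.approx(
            2 * math.asin(math.sqrt(0.8)) - 2 * math.asin(math.sqrt(0.3))
        )
        assert h == pytest.approx(1.0550, abs=5e-4)
        assert n == 14

    @given(
        st.floats(0.05, 0.95), st.floats(0.05, 0.95)
    )
    def test_arcsine_h_complement_symmetry(self, p1, p2):
        if abs(p1 - p2) < 1e-6:
            return
        h1, _ = sample_size_two_prop(PowerSpec(proportions=(p1, p2)))
        h2, _ = sample_size_two_prop(PowerSpec(proportions=(1 - p2, 1 - p1)))
        assert h1 == pytest.approx(h2, rel=1e-9)

    def test_power_spec_validation(self):
        with pytest.raises(ValueError):
            PowerSpec(alpha=1.5, cohens_d=0.8)
        with pytest.raises(ValueError):
            PowerSpec(cohens_d=0.8, proportions=(0.3, 0.8))
        with pytest.raises(ValueError):
            sample_size_two_prop(PowerSpec(proportions=(0.4, 0.4)))
        with pytest.raises(ValueError):
            sample_size_t(PowerSpec(proportions=(0.3, 0.8)))


# ---------------------------------------------------------------------------
# Figure-style analysis driver
# ---------------------------------------------------------------------------

class TestFigureAnalysis:
    @staticmethod
    def _head_group(p, n, treatment):
        return [
            HeadResponseRecord(f"{treatment}-{i}", "wt", treatment, "day1",
                               i < round(p * n))
            for i in range(n)
        ]

    def test_identical_groups_all_ns(self, rng):
        base = rng.gamma(4, 1, 20)
        dataset = {"a": base.tolist(), "b": base.tolist(), "c": base.tolist()}
        plan = {
            "families": [
                {"name": "f", "test": "t_hochberg",
                 "comparisons": [["a", "b"], ["a", "c"]]}
            ]
        }
        table = run_figure_analysis(dataset, plan)
        assert (table["code"] == "ns").all()

    def test_codes_come_from_adjusted_p_in_multi_comparison_family(self, rng):
        dataset = {
            "buffer": rng.gamma(16, 10 / 16, 40).tolist(),
            "repellent": rng.gamma(16, 3 / 16, 40).tolist(),
            "sds": rng.gamma(16, 2 / 16, 40).tolist(),
        }
        plan = {
            "families": [
                {"name": "tail", "test": "t_hochberg",
                 "comparisons": [["repellent", "buffer"], ["repellent", "sds"]]}
            ]
        }
        table = run_figure_analysis(dataset, plan)
        assert table["p_adjusted"].notna().all()
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()
        for _, row in table.iterrows():
            assert row["code"] == significance_code(row["p_adjusted"])

    def test_z_family_on_head_records(self):
        dataset = {
            "buffer": self._head_group(0.2, 40, "buffer"),
            "repellent": self._head_group(0.8, 40, "repellent"),
        }
        plan = {"families": [{"name": "head", "test": "z",
                              "comparisons": [["repellent", "buffer"]]}]}
        table = run_figure_analysis(dataset, plan)
        assert len(table) == 1
        assert table.loc[0, "code"] == "***"
        assert table.loc[0, "statistic_name"] == "z"

    def test_absent_groups_listed_in_error(self):
        plan = {"families": [{"name": "f", "test": "t_hochberg",
                              "comparisons": [["a", "missing1"], ["missing2", "a"]]}]}
        with pytest.raises(ValueError, match=r"missing1.*missing2"):
            run_figure_analysis({"a": [1.0, 2.0]}, plan)

    @pytest.mark.parametrize(
        "p, code",
        [(0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.2, "ns")],
    )
    def test_significance_codes(self, p, code):
        assert significance_code(p) == code
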