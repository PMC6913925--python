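"""Summary tables, group contrasts, and the feces-proximity tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trayquant.stats import (
    compare_groups,
    compare_groups_table,
    feces_proximity_test,
    significance_tier,
    summarize,
)


def results_frame(rows):
    """rows: (sample_type, group, log10_value, censoring)."""
    return pd.DataFrame(
        [
            {
                "sample_type": st,
                "category": grp,
                "log10_value": v,
                "censoring": cens,
            }
            for st, grp, v, cens in rows
        ]
    )


def strata_with_means(mean_a, mean_b, n=10, spread=0.5, sample_type="x"):
    """Two strata whose sample means are exactly the requested values."""
    half = n // 2
    a = [mean_a - spread] * half + [mean_a + spread] * half
    b = [mean_b - spread] * half + [mean_b + spread] * half
    return results_frame(
        [(sample_type, "A", v, "interval_ok") for v in a]
        + [(sample_type, "B", v, "interval_ok") for v in b]
    )


class TestSummarize:
    def test_single_sample_stratum(self):
        df = results_frame([("soil", "low_income", 2.0, "interval_ok")])
        out = summarize(df, "category")
        assert out.loc[0, "mean"] == 2.0
        assert out.loc[0, "sd"] == 0.0
        assert out.loc[0, "n"] == 1

    def test_two_sample_mean_and_sample_sd(self):
        df = results_frame(
            [
                ("soil", "g", 1.0, "interval_ok"),
                ("soil", "g", 3.0, "interval_ok"),
            ]
        )
        out = summarize(df, "category")
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "sd"] == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_percent_positive_counts_non_left_censored(self):
        df = results_frame(
            [
                ("soil", "g", -0.3, "left"),
                ("soil", "g", 2.0, "interval_ok"),
                ("soil", "g", 5.0, "right"),
                ("soil", "g", 1.0, "interval_ok"),
            ]
        )
        out = summarize(df, "category")
        assert out.loc[0, "percent_positive"] == pytest.approx(75.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rows = [
            ("soil", "g", float(v), "interval_ok")
            for v in rng.normal(2, 1, 30)
        ]
        a = summarize(results_frame(rows), "category")
        b = summarize(results_frame(rows[::-1]), "category")
        pd.testing.assert_frame_equal(a, b)

    def test_equal_size_strata_pool_to_mean_of_means(self):
        rng = np.random.default_rng(7)
        rows = []
        for grp in ("n1", "n2", "n3"):
            rows += [
                ("soil", grp, float(v), "interval_ok")
                for v in rng.normal(2, 1, 10)
            ]
        df = results_frame(rows)
        per_group = summarize(df, "category")["mean"]
        df_all = df.assign(category="all")
        pooled = summarize(df_all, "category").loc[0, "mean"]
        assert pooled == pytest.approx(per_group.mean())


class TestCompareGroups:
    def test_antisymmetry(self):
        df = strata_with_means(3.0, 1.5)
        ab = compare_groups(df, "category", "A", "B", sample_type="x")
        ba = compare_groups(df, "category", "B", "A", sample_type="x")
        assert ab.mean_difference == pytest.approx(-ba.mean_difference)
        assert ab.ci_low == pytest.approx(-ba.ci_high)

    def test_equal_strata_give_zero_difference(self):
        df = strata_with_means(2.0, 2.0)
        cmp = compare_groups(df, "category", "A", "B", sample_type="x")
        assert cmp.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert cmp.ci_low < 0 < cmp.ci_high
        assert not cmp.significant

    def test_shift_equivariance(self):
        df = strata_with_means(2.5, 1.0)
        base = compare_groups(df, "category", "A", "B", sample_type="x")
        shifted = df.copy()
        shifted.loc[shifted["category"] == "A", "log10_value"] += 0.7
        moved = compare_groups(shifted, "category", "A", "B", sample_type="x")
        assert moved.mean_difference == pytest.approx(
            base.mean_difference + 0.7
        )

    def test_ci_equals_delta_plus_minus_1p96_se(self):
        # hand computation from the pooled two-sample formula
        rng = np.random.default_rng(11)
        a = rng.normal(3.0, 1.0, 40)
        b = rng.normal(1.0, 1.0, 40)
        df = results_frame(
            [("x", "A", float(v), "interval_ok") for v in a]
            + [("x", "B", float(v), "interval_ok") for v in b]
        )
        cmp = compare_groups(df, "category", "A", "B", sample_type="x")
        delta = a.mean() - b.mean()
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        se = math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert cmp.mean_difference == pytest.approx(delta)
        assert cmp.ci_high - cmp.mean_difference == pytest.approx(
            1.96 * se, rel=1e-3
        )

    def test_small_stratum_suppressed(self):
        df = results_frame(
            [
                ("x", "A", 1.0, "interval_ok"),
                ("x", "B", 2.0, "interval_ok"),
                ("x", "B", 3.0, "interval_ok"),
            ]
        )
        with pytest.warns(UserWarning):
            assert (
                compare_groups(df, "category", "A", "B", sample_type="x")
                is None
            )

    def test_empty_stratum_rejected(self):
        df = results_frame([("x", "A", 1.0, "interval_ok")])
        with pytest.raises(ValueError):
            compare_groups(df, "category", "A", "B", sample_type="x")

    def test_table_has_one_row_per_sample_type(self):
        df = pd.concat(
            [
                strata_with_means(3.0, 1.0, sample_type="soil"),
                strata_with_means(5.0, 4.0, sample_type="surface_water"),
            ],
            ignore_index=True,
        )
        table = compare_groups_table(df, "category", "A", "B")
        assert sorted(table["sample_type"]) == ["soil", "surface_water"]

    def test_significance_tiers(self):
        assert significance_tier(0.2) == ""
        assert significance_tier(0.04) == "*"
        assert significance_tier(0.004) == "**"
        assert significance_tier(0.0004) == "***"


class TestPrintedGroupMeanContrasts:
    """Contrasts between strata constructed to have the study's printed
    category means must reproduce the printed mean differences."""

    @pytest.mark.parametrize(
        "sample_type, mean_a, mean_b, printed_delta",
        [
            ("surface_water", 6.21, 4.29, 1.92),  # low vs high income
            ("bathing_water", 1.92, 0.94, 0.98),  # low vs high income
            ("floodwater", 4.86, 4.38, 0.48),  # low vs high income
            ("soil", 3.09, 1.63, 1.46),  # floating vs high income
            ("municipal_water", 0.46, 1.89, -1.43),  # DNCC vs DSCC
        ],
    )
    def test_delta_matches_printed_difference(
        self, sample_type, mean_a, mean_b, printed_delta
    ):
        df = strata_with_means(mean_a, mean_b, n=40, sample_type=sample_type)
        cmp = compare_groups(df, "category", "A", "B", sample_type=sample_type)
        assert cmp.mean_difference == pytest.approx(printed_delta, abs=1e-9)


class TestFecesProximity:
    def test_identical_groups_no_effect(self):
        x = np.array([1.0, 2.0, 3.0])
        out = feces_proximity_test(x, x.copy())
        assert out["t_statistic"] == 0.0
        assert out["t_p_value"] == 1.0

    def test_rank_sum_matches_exhaustive_enumeration(self):
        near, far = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        out = feces_proximity_test(near, far)
        # oracle: enumerate all C(6,3)=20 assignments of ranks to group 1
        pooled = np.concatenate([near, far])
        ranks = pooled.argsort().argsort() + 1
        obs_sum = ranks[:3].sum()
        sums = [
            sum(c) for c in itertools.combinations(range(1, 7), 3)
        ]
        p_exact = np.mean(
            [
                (s <= min(obs_sum, 21 - obs_sum))
                or (s >= max(obs_sum, 21 - obs_sum))
                for s in sums
            ]
        )
        assert out["rank_sum_p_value"] == pytest.approx(p_exact)
        # U statistic = rank sum - n(n+1)/2 for one of the two groups
        assert out["rank_sum_statistic"] in (0.0, 9.0)

    def test_tied_inputs_handled(self):
        out = feces_proximity_test(
            np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 2.0])
        )
        assert 0 <= out["rank_sum_p_value"] <= 1

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            feces_proximity_test(np.array([]), np.array([1.0]))

    def test_clear_separation_is_significant(self):
        rng = np.random.default_rng(5)
        near = rng.normal(3.0, 0.5, 30)
        far = rng.normal(1.0, 0.5, 30)
        out = feces_proximity_test(near, far)
        assert out["t_p_value"] < 1e-6
        assert out["rank_sum_p_value"] < 1e-6
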