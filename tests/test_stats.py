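"""ANOVA + Scheffé, chi-square, Mann-Whitney and clinical correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gratiomap.stats import (
    chi_square_independence,
    compare_cohort,
    correlate_clinical,
    mann_whitney_z,
    oneway_anova_scheffe,
)


def anova_bruteforce(groups):
    """Explicit sum-of-squares one-way ANOVA, the independent oracle."""
    data = [np.asarray(g, float) for g in groups]
    grand = np.concatenate(data).mean()
    k = len(data)
    n = sum(d.size for d in data)
    ss_between = sum(d.size * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = sps.f.sf(f, k - 1, n - k)
    return f, p


class TestAnova:
    def test_identical_groups(self):
        res = oneway_anova_scheffe(
            {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        )
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p_overall == pytest.approx(1.0)

    def test_known_three_group_value(self):
        # oracle: SS_between = 16, SS_within = 1.5 -> F = 8 / 0.5 = 16
        groups = {"a": [1, 2], "b": [3, 4], "c": [5, 6]}
        f_oracle, p_oracle = anova_bruteforce(groups.values())
        assert f_oracle == pytest.approx(16.0, abs=1e-12)
        res = oneway_anova_scheffe(groups)
        assert res.F == pytest.approx(f_oracle, abs=1e-10)
        assert res.p_overall == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_bruteforce_on_random_data(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            groups = {
                f"g{i}": rng.normal(i * 0.3, 1.0, rng.integers(3, 8))
                for i in range(rng.integers(2, 5))
            }
            f_oracle, _ = anova_bruteforce(groups.values())
            res = oneway_anova_scheffe(groups)
            assert res.F == pytest.approx(f_oracle, abs=1e-10)

    def test_scheffe_two_groups_equals_anova(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.normal(0, 1, 6), "b": rng.normal(0.5, 1, 9)}
        res = oneway_anova_scheffe(groups)
        assert res.pairwise[("a", "b")] == pytest.approx(res.p_overall, abs=1e-12)

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="zero within-group"):
            res = oneway_anova_scheffe({"a": [1, 1], "b": [2, 2]})
        assert np.isinf(res.F)
        assert res.p_overall == 0.0

    def test_all_identical_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            res = oneway_anova_scheffe({"a": [1, 1], "b": [1, 1]})
        assert np.isnan(res.F)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova_scheffe({"a": [1.0], "b": [2.0, 3.0]})


class TestChiSquare:
    def test_cohort_sex_table(self):
        # 9/11 male/female patients vs 3/2 controls
        stat, p = chi_square_independence([[9, 3], [11, 2]])
        assert stat == pytest.approx(0.361, abs=1e-3)
        # p from chi2(df=1) at 0.361; asserted against the distribution,
        # not a printed rounding
        assert p == pytest.approx(sps.chi2.sf(0.3605769230769231, 1), abs=1e-9)

    def test_perfect_independence(self):
        stat, _ = chi_square_independence([[5, 5], [5, 5]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_transpose_invariance(self):
        t = np.array([[9, 3], [11, 2]])
        assert chi_square_independence(t)[0] == pytest.approx(
            chi_square_independence(t.T)[0], abs=1e-12
        )

    def test_matches_formula_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(1, 30, (2, 2)).astype(float)
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            oracle = ((t - expected) ** 2 / expected).sum()
            assert chi_square_independence(t)[0] == pytest.approx(
                oracle, abs=1e-10
            )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 3]])


class TestMannWhitney:
    def test_extreme_separation(self):
        # U = 0; z = -2 / sqrt(5/3) = -1.549
        u, z, _ = mann_whitney_z([1, 2], [3, 4])
        assert u == 0
        assert z == pytest.approx(-1.549, abs=1e-3)

    def test_identical_samples_symmetric(self):
        _, z, _ = mann_whitney_z([1, 2, 3], [1, 2, 3])
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.0], [2.0, 4.0, 5.5]
        _, z_ab, _ = mann_whitney_z(a, b)
        _, z_ba, _ = mann_whitney_z(b, a)
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    def test_u_matches_scipy(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.4, 1, 15)
        u, _, _ = mann_whitney_z(a, b)
        assert u == sps.mannwhitneyu(a, b, alternative="two-sided").statistic

    def test_all_tied_warns(self):
        with pytest.warns(UserWarning):
            _, z, _ = mann_whitney_z([1, 1], [1, 1])
        assert z == 0.0


def _cohort_frame(values, mjoa, tract="lcst", metric="avf"):
    n = len(values)
    return pd.DataFrame(
        {
            "subject_id": [f"P{i}" for i in range(n)],
            "side": ["left"] * n,
            "group": ["affected"] * n,
            "tract": [tract] * n,
            "metric": [metric] * n,
            "value": values,
            "mjoa": mjoa,
            "n_levels": np.ones(n),
        }
    )


class TestClinicalCorrelation:
    def test_monotone_function_perfect_rho(self):
        mjoa = np.arange(10, 18)
        table = _cohort_frame(2.0 * mjoa + 3.0, mjoa)
        out = correlate_clinical(table)
        row = out[(out.clinical == "mjoa")].iloc[0]
        assert row.rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        mjoa = np.arange(10, 18)
        table = _cohort_frame(-1.0 * mjoa, mjoa)
        out = correlate_clinical(table)
        row = out[(out.clinical == "mjoa")].iloc[0]
        assert row.rho == pytest.approx(-1.0)

    def test_constant_column_gives_nan(self):
        mjoa = np.arange(10, 18)
        table = _cohort_frame(np.full(8, 0.5), mjoa)
        out = correlate_clinical(table)
        assert np.isnan(out[(out.clinical == "mjoa")].iloc[0].rho)

    def test_null_calibration(self):
        # independent columns: rejection rate at alpha=0.05 stays nominal
        rng = np.random.default_rng(2024)
        n, reps = 40, 1000
        rejections = 0
        rhos = []
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p = sps.spearmanr(x, y)
            rhos.append(rho)
            rejections += p < 0.05
        assert abs(np.mean(rhos)) <= 0.02
        assert abs(rejections / reps - 0.05) <= 0.02


class TestCompareCohort:
    def test_group_comparison_layout(self):
        rng = np.random.default_rng(5)
        rows = []
        for grp, shift, n in (("affected", -0.05, 12), ("unaffected", 0.0, 8),
                              ("control", 0.0, 10)):
            for i in range(n):
                for tract in ("lcst", "fasciculus_gracilis"):
                    for metric in ("avf", "mvf"):
                        base = 0.35 if metric == "avf" else 0.32
                        eff = shift if metric == "avf" else 0.0
                        rows.append(
                            {"subject_id": f"{grp}{i}", "side": "left",
                             "group": grp, "tract": tract, "metric": metric,
                             "value": base + eff + rng.normal(0, 0.01),
                             "mjoa": 15, "n_levels": 1}
                        )
        res = compare_cohort(pd.DataFrame(rows))
        assert len(res) == 4  # 2 tracts x 2 metrics
        avf_rows = res[res.metric == "avf"]
        assert (avf_rows["sig_affected_vs_control"]).all()

    def test_single_group_rejected(self):
        table = _cohort_frame(np.arange(5.0), np.arange(5))
        with pytest.raises(ValueError, match="2 groups"):
            compare_cohort(table)
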