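import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootzn import anova_lsd, density_folds, group_summary, pearson_matrix, percent_fine_roots
from rootzn.exceptions import RootznError
from rootzn.fieldstats import significance_code


class TestGroupSummary:
    def test_identical_values(self):
        df = pd.DataFrame({"g": ["a"] * 4, "x": [7.0] * 4})
        out = group_summary(df, by=["g"], values=["x"])
        row = out.iloc[0]
        assert row["mean"] == 7.0 and row["se"] == 0.0 and row["n"] == 4

    def test_hand_computed_se(self):
        df = pd.DataFrame({"g": ["a"] * 4, "x": [1.0, 2.0, 3.0, 4.0]})
        row = group_summary(df, by=["g"], values=["x"]).iloc[0]
        assert row["mean"] == pytest.approx(2.5)
        assert row["se"] == pytest.approx(0.6455, abs=1e-4)  # sd/sqrt(n) by hand

    def test_empty_cell_missing_not_zero(self):
        df = pd.DataFrame({"g": ["a", "b"], "x": [1.0, np.nan]})
        out = group_summary(df, by=["g"], values=["x"])
        assert set(out["g"]) == {"a"}  # the all-NaN cell is absent

    def test_biomass_fold_from_reference_means(self):
        from rootzn.reference import TREATMENT_MEANS

        dw = TREATMENT_MEANS["total_dw_mg"]["minusZn"]
        assert round(dw[28] / dw[7]) == 10


class TestAnovaLsd:
    def test_identical_groups_no_pairs(self):
        res = anova_lsd([5.0] * 8, ["a"] * 4 + ["b"] * 4)
        assert res.pairwise_significant == frozenset()
        assert res.protected

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        vals = np.r_[rng.normal(0, 0.01, 4), rng.normal(10, 0.01, 4)]
        res = anova_lsd(vals, ["a"] * 4 + ["b"] * 4)
        assert not res.protected
        assert ("a", "b") in res.pairwise_significant

    def test_lsd_closed_form_oracle(self):
        # 3 genotypes, n=4, data constructed with exact MSE = 1
        cell = np.array([-1.5, -0.5, 0.5, 1.5]) * np.sqrt(1 / np.var([-1.5, -0.5, 0.5, 1.5], ddof=1))
        vals = np.r_[cell, cell + 50.0, cell + 100.0]
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = anova_lsd(vals, groups)
        expected = stats.t.ppf(0.975, 9) * np.sqrt(2 * 1.0 / 4)
        assert res.lsd_05 == pytest.approx(expected, rel=1e-9)
        assert res.pairwise_significant == {("a", "b"), ("b", "c"), ("a", "c")}

    def test_protection_invariant_on_null_data(self):
        # family-wise significance rate on null data stays near alpha
        rng = np.random.default_rng(123)
        n_sims, hits = 300, 0
        for _ in range(n_sims):
            vals = rng.normal(0, 1, 20)
            groups = np.repeat([f"g{i}" for i in range(5)], 4)
            if anova_lsd(vals, groups).pairwise_significant:
                hits += 1
        rate = hits / n_sims
        mc_se = np.sqrt(0.05 * 0.95 / n_sims)
        assert rate <= 0.05 + 3 * mc_se

    def test_insufficient_replication_rejected(self):
        with pytest.raises(RootznError):
            anova_lsd([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_significance_codes(self):
        assert significance_code(0.005) == "**"
        assert significance_code(0.03) == "*"
        assert significance_code(0.2) == "ns"


class TestPearsonMatrix:
    def test_self_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        assert pearson_matrix(df).loc["x", "x"] == 1.0

    def test_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"x": x, "y": -x})
        assert pearson_matrix(df).loc["x", "y"] == pytest.approx(-1.0)

    def test_known_latent_correlation(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=500)
        x = z
        y = 0.8 * z + np.sqrt(1 - 0.64) * rng.normal(size=500)
        r = pearson_matrix(pd.DataFrame({"x": x, "y": y})).loc["x", "y"]
        assert r == pytest.approx(0.8, abs=0.06)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        m = pearson_matrix(df)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.abs(m.values) <= 1.0 + 1e-12)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            m = pearson_matrix(df)
        assert np.isnan(m.loc["x", "c"])

    def test_too_few_rows(self):
        with pytest.raises(RootznError):
            pearson_matrix(pd.DataFrame({"x": [1.0, 2.0]}))


def _density_df(uptake_by_density, rootdw_by_density, n=4):
    rows = []
    for d, u in uptake_by_density.items():
        for _ in range(n):
            rows.append(
                {
                    "hill_density": d,
                    "net_zn_uptake_ug": u,
                    "root_dw_mg": rootdw_by_density[d],
                }
            )
    return pd.DataFrame(rows)


class TestDensityFolds:
    def test_published_fold_combination(self):
        df = _density_df({1: 1.0, 4: 10.0}, {1: 100.0, 4: 250.0})
        out = density_folds(df)
        assert out.loc[4, "uptake_fold"] == pytest.approx(10.0)
        assert out.loc[4, "root_dw_fold"] == pytest.approx(2.5)
        assert out.loc[4, "efficiency_fold"] == pytest.approx(4.0)
        assert out.loc[4, "efficiency_fold_display"] == 4

    def test_equal_folds_unit_efficiency(self):
        df = _density_df({1: 1.0, 4: 3.0}, {1: 100.0, 4: 300.0})
        assert density_folds(df).loc[4, "efficiency_fold"] == pytest.approx(1.0)

    def test_per_hill_scales_with_density(self):
        df = _density_df({1: 2.0, 2: 2.0, 4: 2.0}, {1: 1.0, 2: 1.0, 4: 1.0})
        out = density_folds(df)
        assert out["uptake_per_hill"].tolist() == pytest.approx([2.0, 4.0, 8.0])

    def test_unit_invariance(self):
        df = _density_df({1: 1.0, 4: 10.0}, {1: 100.0, 4: 250.0})
        scaled = df.assign(net_zn_uptake_ug=df["net_zn_uptake_ug"] * 1000.0)
        pd.testing.assert_frame_equal(
            density_folds(df)[["uptake_fold", "root_dw_fold", "efficiency_fold"]],
            density_folds(scaled)[["uptake_fold", "root_dw_fold", "efficiency_fold"]],
        )

    def test_missing_baseline_density(self):
        df = _density_df({2: 1.0, 4: 10.0}, {2: 1.0, 4: 2.0})
        with pytest.raises(RootznError, match="baseline"):
            density_folds(df)


class TestPercentFineRoots:
    def test_half(self):
        assert percent_fine_roots(50, 30, 20) == pytest.approx(0.5)

    def test_zero_fine(self):
        assert percent_fine_roots(0, 30, 20) == 0.0

    def test_equal_thirds(self):
        assert percent_fine_roots(1, 1, 1) == pytest.approx(1 / 3)

    def test_zero_total_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(percent_fine_roots(0, 0, 0))
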