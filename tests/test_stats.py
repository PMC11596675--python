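import numpy as np
import pandas as pd
import pytest

from nadomics import nadome_stats as ns


def _quant(records):
    return pd.DataFrame(records, columns=[
        "analyte", "sample_id", "timepoint", "bio_rep",
        "conc_nmol_per_gcdw", "censored", "outlier",
    ])


class TestRedoxRatios:
    def test_simple_ratio(self):
        q = _quant([
            ("NADH", "s1", "T1", 1, 50.0, False, False),
            ("NAD+", "s1", "T1", 1, 500.0, False, False),
        ])
        out = ns.redox_ratios(q)
        row = out[out["ratio"] == "NADH/NAD+"].iloc[0]
        assert row["value"] == pytest.approx(0.1)

    def test_equal_pools_ratio_one(self):
        q = _quant([
            ("NADPH", "s1", "T1", 1, 80.0, False, False),
            ("NADP+", "s1", "T1", 1, 80.0, False, False),
        ])
        out = ns.redox_ratios(q)
        assert out[out["ratio"] == "NADPH/NADP+"]["value"].iloc[0] == 1.0

    def test_censored_member_skips_sample(self):
        q = _quant([
            ("NADPH", "s1", "T1", 1, 80.0, True, False),
            ("NADP+", "s1", "T1", 1, 80.0, False, False),
        ])
        out = ns.redox_ratios(q)
        assert "NADPH/NADP+" not in set(out.get("ratio", []))

    def test_ratio_identity_per_sample(self):
        rng = np.random.default_rng(4)
        recs = []
        for s in range(6):
            for a in ("NAD+", "NADH", "NADP+", "NADPH"):
                recs.append((a, f"s{s}", "T1", 1, rng.uniform(10, 500), False, False))
        out = ns.redox_ratios(_quant(recs)).pivot(
            index="sample_id", columns="ratio", values="value")
        lhs = out["NADPH/NADH"]
        rhs = out["NADPH/NADP+"] * out["NADP+/NAD+"] / out["NADH/NAD+"]
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


class TestAnovaTukey:
    def test_hand_computed_f_and_p(self):
        res = ns.one_way_anova_tukey({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        # SSB = 13.5, SSW = 4 on (1, 4) df -> F = 13.5
        assert res.f_statistic == pytest.approx(13.5)
        assert res.p_value == pytest.approx(0.02131, abs=2e-4)

    def test_identical_groups(self):
        res = ns.one_way_anova_tukey({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_with_difference_reports_p_zero(self):
        res = ns.one_way_anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.p_value == 0.0
        assert res.pairwise["p_tukey"].iloc[0] == 0.0

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            ns.one_way_anova_tukey({"a": [1.0], "b": [1.0, 2.0]})

    def test_pairwise_p_matches_statsmodels_tukey(self):
        # independent cross-check against the exact statsmodels implementation
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(19)
        groups = {t: rng.normal(m, 1, 4) for t, m in
                  [("T1", 0.0), ("T2", 1.0), ("T3", 3.0), ("T4", 0.5)]}
        res = ns.one_way_anova_tukey(groups)
        vals = np.concatenate(list(groups.values()))
        codes = np.concatenate([[g] * 4 for g in groups])
        ref = pairwise_tukeyhsd(vals, codes)
        # table interpolation clips at [0.001, 0.9]; compare within that band
        exact = np.clip(ref.pvalues, 0.001, 0.9)
        ours = np.clip(res.pairwise["p_tukey"].to_numpy(), 0.001, 0.9)
        # interpolation is coarsest far from the decision thresholds
        np.testing.assert_allclose(ours, exact, atol=0.02)
        near_threshold = exact <= 0.1
        np.testing.assert_allclose(ours[near_threshold], exact[near_threshold], atol=1e-3)
        np.testing.assert_allclose(res.pairwise["meandiff"], ref.meandiffs, rtol=1e-9)

    def test_tukey_pairs_cover_all_contrasts(self):
        res = ns.one_way_anova_tukey({
            "T1": [1.0, 1.1], "T2": [2.0, 2.1], "T3": [3.0, 3.1],
        })
        assert len(res.pairwise) == 3


class TestLog2FoldChanges:
    def _quant_two_groups(self, ref_vals, t2_vals, analyte="NAM"):
        recs = []
        for b, v in enumerate(ref_vals, 1):
            recs.append((analyte, f"T1b{b}", "T1", b, v, False, False))
        for b, v in enumerate(t2_vals, 1):
            recs.append((analyte, f"T2b{b}", "T2", b, v, False, False))
        return _quant(recs)

    def test_doubling_is_plus_one(self):
        fc = ns.log2_fold_changes(self._quant_two_groups(
            [100.0, 100.0], [200.0, 200.0]))
        assert fc["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_equal_means_zero(self):
        fc = ns.log2_fold_changes(self._quant_two_groups(
            [100.0, 110.0], [100.0, 110.0]))
        assert fc["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_quartering_is_minus_two(self):
        fc = ns.log2_fold_changes(self._quant_two_groups(
            [100.0, 100.0], [25.0, 25.0]))
        assert fc["log2fc"].iloc[0] == pytest.approx(-2.0)

    def test_technical_replicates_averaged_within_bio_rep(self):
        # 5 technical reps per bio rep collapse to bio-rep means first
        recs = []
        for b in (1, 2):
            for t in range(5):
                recs.append(("NAM", f"T1b{b}t{t}", "T1", b, 100.0 + t, False, False))
                recs.append(("NAM", f"T2b{b}t{t}", "T2", b, 2 * (100.0 + t), False, False))
        fc = ns.log2_fold_changes(_quant(recs))
        assert fc["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_fdr_adjusts_across_analytes_within_contrast(self):
        rng = np.random.default_rng(12)
        recs = []
        for a in [f"A{i}" for i in range(8)]:
            for tp in ("T1", "T2"):
                for b in (1, 2, 3):
                    recs.append((a, f"{a}{tp}b{b}", tp, b,
                                 rng.normal(100, 5), False, False))
        fc = ns.log2_fold_changes(_quant(recs))
        assert (fc["p_adjusted"] >= fc["p_tukey"] - 1e-12).all()

    def test_stars_thresholds(self):
        assert ns.significance_stars(0.0005) == "***"
        assert ns.significance_stars(0.005) == "**"
        assert ns.significance_stars(0.05) == "*"
        assert ns.significance_stars(0.06) == "ns"


class TestAutoscalePCA:
    def test_perfectly_correlated_pair_pc1_100(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        wide = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = ns.autoscale_pca(wide)
        assert res.variance_explained[0] == pytest.approx(100.0)

    def test_orthogonal_equal_variance_split_50_50(self):
        wide = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0], "b": [1.0, 1.0, -1.0, -1.0]})
        res = ns.autoscale_pca(wide)
        np.testing.assert_allclose(res.variance_explained, [50.0, 50.0], atol=1e-9)

    def test_variance_explained_sums_to_100(self):
        rng = np.random.default_rng(8)
        wide = pd.DataFrame(rng.normal(size=(10, 6)),
                            columns=[f"m{i}" for i in range(6)])
        res = ns.autoscale_pca(wide)
        assert res.variance_explained.sum() == pytest.approx(100.0)
        assert (np.diff(res.variance_explained) <= 1e-9).all()

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(8)
        wide = pd.DataFrame(rng.normal(size=(12, 5)),
                            columns=[f"m{i}" for i in range(5)])
        res = ns.autoscale_pca(wide)
        gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_planted_two_factor_structure_recovered(self):
        rng = np.random.default_rng(21)
        n = 10
        f1 = rng.normal(size=n)
        f2 = rng.normal(size=n)
        cols = {}
        for i in range(3):
            cols[f"x{i}"] = f1 + 0.05 * rng.normal(size=n)
        for i in range(3):
            cols[f"y{i}"] = f2 + 0.05 * rng.normal(size=n)
        res = ns.autoscale_pca(pd.DataFrame(cols))
        assert res.variance_explained[:2].sum() >= 95.0

    def test_zero_variance_column_dropped_with_warning(self):
        wide = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = ns.autoscale_pca(wide)
        assert list(res.loadings.index) == ["a"]

    def test_sqrt_sd_scaling_option(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        wide = pd.DataFrame({"a": x, "b": 10 * x[::-1]})
        res_sd = ns.autoscale_pca(wide, scaling="sd")
        res_sqrt = ns.autoscale_pca(wide, scaling="sqrt_sd")
        assert res_sd.variance_explained[0] == pytest.approx(100.0)
        assert res_sqrt.variance_explained[0] == pytest.approx(100.0)
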