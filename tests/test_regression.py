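"""Region-model layer: OLS inference, backward elimination, BH-FDR,
lobe summaries and the two-feature-set comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from actibrain.atlas import load_atlas
from actibrain.regression import (
    RegionModelResult,
    backward_eliminate,
    bh_fdr,
    compare_feature_sets,
    export_violin_data,
    fit_all_regions,
    fit_ols,
    lobe_summary,
    results_frame,
)


@pytest.fixture(scope="module")
def atlas():
    return load_atlas()


class TestFitOls:
    def test_hand_dataset_exact_coefficients(self):
        x = np.arange(1.0, 6.0)
        fit = fit_ols(2 * x + 1, x[:, None])
        np.testing.assert_allclose(fit.params, [1.0, 2.0], atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_linear_relation_gives_r2_one(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ [1.0, -2.0, 0.5] + 4.0
        fit = fit_ols(y, X)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-9)

    def test_null_slope_within_sampling_error(self, rng):
        n = 5000
        x = rng.standard_normal((n, 1))
        y = rng.standard_normal(n)
        fit = fit_ols(y, x)
        assert abs(fit.params[1]) < 3 * fit.bse[1]

    def test_matches_statsmodels_inference(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.standard_normal((60, 5))
        y = X[:, 0] + rng.standard_normal(60)
        mine = fit_ols(y, X)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(mine.params, ref.params, rtol=1e-10)
        np.testing.assert_allclose(mine.pvalues, ref.pvalues, rtol=1e-8)
        assert mine.f_pvalue == pytest.approx(ref.f_pvalue, rel=1e-8)
        assert mine.r_squared == pytest.approx(ref.rsquared, rel=1e-12)

    def test_in_sample_r_squared_identity(self, rng):
        X = rng.standard_normal((50, 4))
        y = X[:, 0] + 0.5 * rng.standard_normal(50)
        fit = fit_ols(y, X)
        r = np.corrcoef(fit.fitted, y)[0, 1]
        assert r**2 == pytest.approx(fit.r_squared, abs=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        X["c"] = X["a"] + X["b"]
        with pytest.raises(ValueError, match="'c'"):
            fit_ols(rng.standard_normal(30), X)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ols(rng.standard_normal(5), rng.standard_normal((5, 4)))


class TestBackwardElimination:
    def test_retains_signal_drops_noise(self):
        # majority over seeds: signal kept alone in most replicates
        kept_alone = 0
        for rep in range(10):
            local = np.random.default_rng(rep)
            n = 200
            X = pd.DataFrame(local.standard_normal((n, 2)), columns=["signal", "noise"])
            y = X["signal"].to_numpy() + 0.2 * local.standard_normal(n)
            _, kept = backward_eliminate(y, X)
            kept_alone += int(kept == ["signal"])
        assert kept_alone >= 8

    def test_alpha_one_retains_every_full_rank_feature(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = rng.standard_normal(40)
        fit, kept = backward_eliminate(y, X, alpha=1.0)
        assert kept == list(X.columns)
        assert fit is not None

    def test_final_model_pvalues_below_alpha(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 20)),
                         columns=[f"f{i:02d}" for i in range(20)])
        y = X["f00"].to_numpy() + rng.standard_normal(100)
        fit, kept = backward_eliminate(y, X, alpha=0.05)
        if fit is not None:
            assert all(p < 0.05 for p in fit.pvalues[1:])

    def test_pure_noise_saturated_start_inflates_in_sample_r(self):
        """n=132, K=124 null: selection alone produces a large in-sample r."""
        local = np.random.default_rng(42)
        X = pd.DataFrame(local.standard_normal((132, 124)),
                         columns=[f"f{i:03d}" for i in range(124)])
        y = local.standard_normal(132)
        fit, kept = backward_eliminate(y, X)
        assert fit is not None
        r = np.corrcoef(fit.fitted, y)[0, 1]
        assert r > 0.3  # far above the ~0.09 null for one pre-chosen feature

    def test_saturated_start_is_prescreened_with_warning(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 40)),
                         columns=[f"f{i:02d}" for i in range(40)])
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="pre-screening"):
            fit, kept = backward_eliminate(y, X)
        assert len(kept) <= 20

    def test_collinear_candidates_handled(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=["a", "b", "c"])
        X["d"] = X["a"] + X["b"]
        y = X["a"].to_numpy() + 0.1 * rng.standard_normal(50)
        fit, kept = backward_eliminate(y, X)
        assert fit is not None  # does not raise


class TestBhFdr:
    def brute(self, p, q):
        m = len(p)
        order = np.argsort(p)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_star = k
        reject = np.zeros(m, dtype=bool)
        reject[order[:k_star]] = True
        return reject

    def test_single_small_p_rejected(self):
        reject, adjusted = bh_fdr(np.array([0.01]), q=0.05)
        assert reject.tolist() == [True]
        assert adjusted[0] == pytest.approx(0.01)

    def test_all_borderline_rejected_at_largest_rank(self):
        p = np.full(116, 0.049)
        reject, _ = bh_fdr(p, q=0.05)
        assert reject.all()

    def test_four_point_example(self):
        # rank thresholds k*q/m = 0.0125, 0.025, 0.0375, 0.05:
        # 0.04 > 0.0375, so the step-up stops at rank 2
        p = np.array([0.01, 0.02, 0.04, 0.50])
        reject, adjusted = bh_fdr(p, q=0.05)
        assert reject.tolist() == [True, True, False, False]
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.05333333, 0.5], rtol=1e-6)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 200))
            p = rng.random(m)
            reject, _ = bh_fdr(p, q=0.05)
            np.testing.assert_array_equal(reject, self.brute(p, 0.05))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(2, 150)))
            reject, adjusted = bh_fdr(p, q=0.05)
            ref_rej, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(reject, ref_rej)
            np.testing.assert_allclose(adjusted, ref_adj, rtol=1e-12)

    def test_rejection_monotone_in_p(self, rng):
        p = rng.random(80)
        reject, _ = bh_fdr(p)
        if reject.any():
            assert reject[p <= p[reject].max()].all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


@pytest.fixture(scope="module")
def generated_fit(atlas):
    """Volumes generated from 5 tf features with low noise, n=300."""
    rng = np.random.default_rng(77)
    n = 300
    cols = [f"tf_{i:02d}" for i in range(1, 25)]
    features = pd.DataFrame(rng.standard_normal((n, len(cols))), columns=cols,
                            index=[f"S{i:04d}" for i in range(n)])
    features.index.name = "subject_id"
    true_cols = cols[:5]
    beta = np.array([1.0, -1.2, 0.8, 1.5, -0.7])
    residuals = pd.DataFrame(index=features.index)
    for name in atlas["region_name"]:
        signal = features[true_cols].to_numpy() @ beta
        residuals[name] = signal + 0.1 * signal.std() * rng.standard_normal(n)
    results = fit_all_regions(features, residuals, atlas)
    return features, residuals, results, true_cols


class TestFitAllRegions:
    def test_one_result_per_region(self, generated_fit):
        results = generated_fit[2]
        assert len(results) == 116

    def test_generative_oracle_high_r_and_significant(self, generated_fit):
        results = generated_fit[2]
        assert all(r.fdr_significant for r in results)
        assert all(r.r > 0.95 for r in results)
        assert all(r.r**2 == pytest.approx(r.r_squared, abs=1e-10) for r in results)

    def test_true_features_retained(self, generated_fit):
        results, true_cols = generated_fit[2], generated_fit[3]
        for r in results[:10]:
            assert set(true_cols) <= set(r.retained_features)

    def test_subject_order_invariance(self, atlas, generated_fit):
        features, residuals = generated_fit[0], generated_fit[1]
        sub_atlas = atlas.head(3)
        base = fit_all_regions(features, residuals, sub_atlas)
        perm = np.random.default_rng(1).permutation(len(features))
        shuffled = fit_all_regions(features.iloc[perm], residuals.iloc[perm], sub_atlas)
        for a, b in zip(base, shuffled):
            assert a.retained_features == b.retained_features
            assert a.r == pytest.approx(b.r, rel=1e-10)

    def test_subject_mismatch_rejected(self, atlas, generated_fit):
        features, residuals = generated_fit[0], generated_fit[1]
        with pytest.raises(ValueError, match="mismatch"):
            fit_all_regions(features.iloc[:-1], residuals, atlas.head(2))


class TestLobeSummary:
    def _fake_results(self, atlas, r_by_lobe):
        out = []
        for _, row in atlas.iterrows():
            r = r_by_lobe.get(row["lobe"], 0.5)
            out.append(RegionModelResult(
                region_id=int(row["region_id"]), region_name=row["region_name"],
                lobe=row["lobe"], retained_features=["x"], coefficients={},
                pvalues={}, r=r, r_squared=r**2, model_p=0.001,
                fdr_significant=True,
            ))
        return out

    def test_constant_lobe_mean_and_zero_sd(self, atlas):
        results = self._fake_results(atlas, {"temporal": 0.9})
        summary = lobe_summary(results, atlas).set_index("lobe")
        assert summary.loc["temporal", "mean_r"] == pytest.approx(0.9)
        assert summary.loc["temporal", "sd_r"] == pytest.approx(0.0)

    def test_lobe_region_counts(self, atlas):
        summary = lobe_summary(self._fake_results(atlas, {}), atlas).set_index("lobe")
        assert summary.loc["temporal", "n_regions"] == 8
        assert summary.loc["frontal", "n_regions"] == 24
        assert "vermis" not in summary.index
        assert summary["n_regions"].sum() == 108

    def test_mean_sd_match_two_pass_computation(self, atlas, rng):
        results = self._fake_results(atlas, {})
        for res in results:
            res.r = float(rng.random())
            res.r_squared = res.r**2
        summary = lobe_summary(results, atlas).set_index("lobe")
        rs = [res.r for res in results if res.lobe == "limbic"]
        assert summary.loc["limbic", "mean_r"] == pytest.approx(np.mean(rs))
        assert summary.loc["limbic", "sd_r"] == pytest.approx(np.std(rs, ddof=1))


class TestComparison:
    def _results(self, atlas, rng, shift=0.0):
        out = []
        for _, row in atlas.iterrows():
            r = 0.7 + 0.2 * rng.random() + shift
            out.append(RegionModelResult(
                region_id=int(row["region_id"]), region_name=row["region_name"],
                lobe=row["lobe"], retained_features=[], coefficients={},
                pvalues={}, r=r, r_squared=r**2 if r <= 1 else 1.0, model_p=0.01,
            ))
        return out

    def test_identical_results_give_p_one(self, atlas, rng):
        a = self._results(atlas, np.random.default_rng(0))
        b = [RegionModelResult(**vars(r)) for r in a]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = compare_feature_sets(a, b, atlas)
        assert (comp["p_correlation"] == 1.0).all()
        assert (comp["mean_diff_r"].abs() < 1e-15).all()

    def test_t_statistic_matches_closed_form(self, atlas):
        rng_a, rng_b = np.random.default_rng(1), np.random.default_rng(2)
        a = self._results(atlas, rng_a, shift=0.05)
        b = self._results(atlas, rng_b)
        comp = compare_feature_sets(a, b, atlas).set_index("lobe")
        by_name = {r.region_name: r for r in b}
        diffs = np.array([r.r - by_name[r.region_name].r
                          for r in a if r.lobe == "frontal"])
        from scipy import stats as sps

        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        p = 2 * sps.t.sf(abs(t), len(diffs) - 1)
        assert comp.loc["frontal", "p_correlation"] == pytest.approx(p, rel=1e-10)

    def test_bonferroni_multiplies_by_nine(self, atlas):
        a = self._results(atlas, np.random.default_rng(3), shift=0.05)
        b = self._results(atlas, np.random.default_rng(4))
        comp = compare_feature_sets(a, b, atlas)
        np.testing.assert_allclose(
            comp["p_correlation_bonferroni"],
            np.minimum(1.0, comp["p_correlation"] * 9),
        )

    def test_region_mismatch_rejected(self, atlas):
        a = self._results(atlas, np.random.default_rng(5))
        with pytest.raises(ValueError, match="mismatch"):
            compare_feature_sets(a, a[:-1], atlas)

    def test_violin_export_rows_and_consistency(self, atlas):
        a = self._results(atlas, np.random.default_rng(6))
        b = self._results(atlas, np.random.default_rng(7))
        long = export_violin_data(a, b, atlas)
        assert len(long) == 216  # 108 non-vermis regions x 2 feature sets
        set_a = long[long["feature_set"] == "dl_tf"]
        by_name = {r.region_name: r.r for r in a}
        for _, row in set_a.iterrows():
            assert row["r"] == by_name[row["region"]]
        # grouping reproduces lobe means
        means = set_a.groupby("lobe")["r"].mean()
        summary = lobe_summary(a, atlas).set_index("lobe")
        for lobe in means.index:
            assert means[lobe] == pytest.approx(summary.loc[lobe, "mean_r"])

    def test_results_frame_layout(self, atlas):
        a = self._results(atlas, np.random.default_rng(8))
        frame = results_frame(a)
        assert len(frame) == 116
        assert {"region_name", "lobe", "r", "r2", "model_p",
                "fdr_adjusted_p", "excluded"} <= set(frame.columns)
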