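"""Discriminant model, metrics, cross-validation, imputation, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hipred.classifier import (
    LDAModel,
    auc,
    cross_validate,
    enrichment_from_counts,
    enrichment_test,
    fit_lda,
    impute_pmm,
    mcc,
    predict_phi,
)
from hipred.simulate import SimulationConfig, simulate_feature_classes

from oracles import gaussian_bayes_posterior, pairwise_auc


class TestFitLda:
    def test_1d_direction_points_toward_hi_mean(self):
        x = np.concatenate([np.random.default_rng(0).normal(3, 1, 50),
                            np.random.default_rng(1).normal(0, 1, 50)])
        y = np.array([1] * 50 + [0] * 50)
        model = fit_lda(x, y)
        assert model.coef[0] > 0

    def test_identical_class_means_warn_degenerate(self):
        base = np.random.default_rng(0).normal(size=(15, 2))
        x = np.vstack([base, base])  # both classes see identical points
        y = np.array([1] * 15 + [0] * 15)
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_lda(x, y)
        assert np.allclose(model.coef, 0)

    def test_recovers_generating_discriminant_direction(self):
        cfg = SimulationConfig(seed=3, n_hi=2000, n_hs=2000)
        x, y, info = simulate_feature_classes(cfg)
        model = fit_lda(x.values, y.values)
        w_raw = model.coef / model.scale  # undo unit-variance scaling
        w_true = info["optimal_discriminant"]
        cos = w_raw @ w_true / (np.linalg.norm(w_raw) * np.linalg.norm(w_true))
        assert cos >= 0.95

    def test_collinear_features_rejected_with_hint(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        x = np.column_stack([a, 2 * a])
        y = np.array([1] * 20 + [0] * 20)
        with pytest.raises(ValueError, match="collinear"):
            fit_lda(x, y)

    def test_incomplete_rows_dropped_and_counted(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 2))
        x[:5, 0] = np.nan
        y = np.array([1] * 15 + [0] * 15)
        model = fit_lda(x, y)
        assert model.n_dropped_incomplete == 5

    def test_json_roundtrip(self):
        cfg = SimulationConfig(seed=5, n_hi=50, n_hs=60)
        x, y, _ = simulate_feature_classes(cfg)
        m = fit_lda(x.values, y.values, feature_names=list(x.columns))
        m2 = LDAModel.from_json(m.to_json())
        np.testing.assert_allclose(m2.coef, m.coef)
        assert m2.feature_names == m.feature_names
        p1 = predict_phi(m, x.values)["phi"]
        p2 = predict_phi(m2, x.values)["phi"]
        np.testing.assert_allclose(p1, p2)


class TestPredictPhi:
    def test_midpoint_with_equal_priors_is_half(self):
        x = np.vstack(
            [np.random.default_rng(0).normal(2, 1, (50, 2)),
             np.random.default_rng(1).normal(-2, 1, (50, 2))]
        )
        y = np.array([1] * 50 + [0] * 50)
        model = fit_lda(x, y, priors=(0.5, 0.5))
        mid = (model.mean_hi + model.mean_hs) / 2 * model.scale
        phi = predict_phi(model, mid[None, :])["phi"].iloc[0]
        assert phi == pytest.approx(0.5, abs=1e-12)

    def test_saturates_at_class_mean_under_large_separation(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(50, 1, 100), rng.normal(0, 1, 100)])
        y = np.array([1] * 100 + [0] * 100)
        model = fit_lda(x, y)
        assert predict_phi(model, np.array([50.0]))["phi"].iloc[0] > 0.999

    def test_posterior_matches_gaussian_bayes_oracle(self):
        """Fitted posterior equals the direct two-density Bayes computation
        evaluated under the model's own estimated Gaussians."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n1, n0 = rng.integers(10, 30, size=2)
            p = int(rng.integers(1, 4))
            mu1, mu0 = rng.normal(size=p), rng.normal(size=p)
            x = np.vstack([rng.normal(mu1, 1.0, (n1, p)),
                           rng.normal(mu0, 1.0, (n0, p))])
            y = np.array([1] * n1 + [0] * n0)
            model = fit_lda(x, y)
            q = rng.normal(size=p)
            phi = predict_phi(model, q[None, :])["phi"].iloc[0]
            oracle = gaussian_bayes_posterior(
                q / model.scale, model.mean_hi, model.mean_hs,
                model.pooled_cov, model.prior_hi,
            )
            assert phi == pytest.approx(oracle, abs=1e-9)

    def test_scaling_invariance_of_phi(self):
        cfg = SimulationConfig(seed=9, n_hi=80, n_hs=90)
        x, y, _ = simulate_feature_classes(cfg)
        m1 = fit_lda(x.values, y.values)
        scaled = x.values * np.array([10.0, 0.5, 3.0, 100.0])
        m2 = fit_lda(scaled, y.values)
        p1 = predict_phi(m1, x.values)["phi"]
        p2 = predict_phi(m2, scaled)["phi"]
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_agrees_with_reference_lda_implementation(self):
        """Direction and posteriors match scikit-learn's LDA (which uses a
        biased covariance estimate, so posteriors agree only closely)."""
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        cfg = SimulationConfig(seed=31, n_hi=1000, n_hs=1000)
        x, y, _ = simulate_feature_classes(cfg)
        model = fit_lda(x.values, y.values)
        ref = sklearn_lda().fit(x.values, y.values)
        w_ref = ref.coef_.ravel()
        w_ours = model.coef / model.scale
        cos = w_ours @ w_ref / (np.linalg.norm(w_ours) * np.linalg.norm(w_ref))
        assert cos == pytest.approx(1.0, abs=1e-10)
        p_ref = ref.predict_proba(x.values)[:, 1]
        p_ours = predict_phi(model, x.values)["phi"].values
        np.testing.assert_allclose(p_ours, p_ref, atol=2e-3)

    def test_missing_features_excluded_and_flagged(self):
        x = np.random.default_rng(0).normal(size=(20, 2))
        y = np.array([1] * 10 + [0] * 10)
        model = fit_lda(x, y)
        q = np.array([[0.0, np.nan], [0.0, 0.0]])
        out = predict_phi(model, q, gene_ids=["a", "b"])
        assert not out.loc["a", "predictable"] and np.isnan(out.loc["a", "phi"])
        assert out.loc["b", "predictable"]


class TestMetrics:
    def test_auc_perfect_and_chance(self):
        assert auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
        assert auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_auc_equals_pair_enumeration_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    def test_auc_equals_mann_whitney_u_identity(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        n1, n0 = labels.sum(), (labels == 0).sum()
        assert auc(scores, labels) == pytest.approx(u / (n1 * n0), abs=1e-12)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((5, 5, 0, 0), 1.0),
            ((5, 0, 5, 0), 0.0),  # zero-factor convention
            ((4, 3, 2, 1), (4 * 3 - 2 * 1) / math.sqrt(6 * 5 * 5 * 4)),
        ],
    )
    def test_mcc_values(self, counts, expected):
        assert mcc(*counts) == pytest.approx(expected, abs=1e-12)


class TestCrossValidation:
    def test_null_features_give_chance_auc(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(1000, 4))
        y = np.array([1] * 500 + [0] * 500)
        cv = cross_validate(x, y, folds=10, repeats=3, seed=2)
        assert 0.45 <= cv.mean_auc <= 0.55

    def test_approaches_generative_optimum(self):
        cfg = SimulationConfig(seed=12, n_hi=1000, n_hs=1000)
        x, y, info = simulate_feature_classes(cfg)
        cv = cross_validate(x.values, y.values, folds=10, repeats=5, seed=3)
        assert cv.mean_auc == pytest.approx(info["optimal_auc"], abs=0.02)

    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(seed=1, n_hi=60, n_hs=70)
        x, y, _ = simulate_feature_classes(cfg)
        a = cross_validate(x.values, y.values, folds=5, repeats=1, seed=17)
        b = cross_validate(x.values, y.values, folds=5, repeats=30, seed=17)
        assert a.auc_per_repeat[0] == b.auc_per_repeat[0]

    def test_too_few_per_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(12, 2))
        y = np.array([1] * 5 + [0] * 7)
        with pytest.raises(ValueError):
            cross_validate(x, y, folds=10)


class TestImputation:
    def test_complete_table_unchanged(self):
        cfg = SimulationConfig(seed=2, n_hi=40, n_hs=40)
        x, _, _ = simulate_feature_classes(cfg)
        out, flag = impute_pmm(x, seed=0)
        pd.testing.assert_frame_equal(out, x)
        assert not flag.any()

    def test_single_donor_copies_nearest_neighbour_value(self):
        t = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 2.05], "b": [1.0, 2.0, 3.0, np.nan]},
            index=list("wxyz"),
        )
        out, flag = impute_pmm(t, seed=0, donors=1)
        # regression of b on a is the identity; prediction 2.05 is nearest
        # to complete case x (pred 2.0), whose observed b is 2.0
        assert out.loc["z", "b"] == 2.0
        assert flag["z"] and not flag["w"]

    def test_imputed_values_are_observed_values(self):
        cfg = SimulationConfig(seed=4, n_hi=150, n_hs=150, missingness_rate=0.2)
        x, _, _ = simulate_feature_classes(cfg)
        out, _ = impute_pmm(x, seed=1)
        assert not out.isna().any().any()
        for col in x.columns:
            observed = set(x[col].dropna())
            imputed_cells = x[col].isna()
            assert set(out.loc[imputed_cells, col]) <= observed

    def test_mcar_means_preserved_within_3_se(self):
        cfg = SimulationConfig(seed=6, n_hi=400, n_hs=400, missingness_rate=0.2)
        x, _, _ = simulate_feature_classes(cfg)
        cfg0 = SimulationConfig(seed=6, n_hi=400, n_hs=400, missingness_rate=0.0)
        full, _, _ = simulate_feature_classes(cfg0)
        out, _ = impute_pmm(x, seed=2)
        for col in x.columns:
            se = full[col].std(ddof=1) / math.sqrt(len(full))
            assert abs(out[col].mean() - full[col].mean()) < 3 * se

    def test_no_complete_cases_rejected(self):
        t = pd.DataFrame({"a": [np.nan, 1.0], "b": [1.0, np.nan]})
        with pytest.raises(ValueError):
            impute_pmm(t, seed=0)


class TestEnrichment:
    def test_dominant_vs_recessive_odds_ratio_arithmetic(self):
        # 87/392 dominant-disease genes vs 39/606 recessive predicted HI
        r = enrichment_from_counts(87, 392 - 87, 39, 606 - 39)
        assert r.fold_enrichment == pytest.approx(4.147, abs=0.001)
        assert r.p_value < 1e-12

    def test_baseline_fold_arithmetic(self):
        r = enrichment_from_counts(
            260, 1063 - 260, 0, 0, "proportion_ratio_vs_baseline", 0.10
        )
        assert r.fold_enrichment == pytest.approx(2.446, abs=0.001)
        r2 = enrichment_from_counts(
            28, 64 - 28, 0, 0, "proportion_ratio_vs_baseline", 0.10
        )
        assert r2.fold_enrichment == pytest.approx(4.375, abs=0.001)

    def test_background_composition_gives_fold_near_one(self):
        rng = np.random.default_rng(10)
        phi = pd.Series(rng.random(2000),
                        index=[f"g{i}" for i in range(2000)])
        set_a = list(rng.choice(phi.index, 400, replace=False))
        r = enrichment_test(phi, set_a)
        assert r.fold_enrichment == pytest.approx(1.0, abs=0.35)

    def test_top_decile_definition(self):
        phi = pd.Series(
            np.linspace(0, 1, 100), index=[f"g{i}" for i in range(100)]
        )
        top = [f"g{i}" for i in range(95, 100)]  # top 5 of 100
        r = enrichment_test(phi, top, top_fraction=0.10)
        assert r.a == 5 and r.b == 0
        assert r.fold_enrichment == pytest.approx(10.0)

    def test_training_overlap_warns(self):
        phi = pd.Series([0.1, 0.9], index=["a", "b"])
        with pytest.warns(UserWarning, match="training"):
            enrichment_test(phi, ["a", "b"], training_genes={"a"})
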