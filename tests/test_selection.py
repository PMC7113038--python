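"""Univariate screen and LASSO-CV selection: null behavior, recovery, determinism."""

import numpy as np
import pandas as pd
import pytest

from radpdl1 import build_signature, lasso_cv_select, rad_score, univariate_screen
from radpdl1.selection import SelectionReport, _l1_logistic


def _noise_features(n, p, seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(0, 1, (n, p)), columns=[f"f{i}" for i in range(p)])
    y = rng.integers(0, 2, n)
    return X, y


class TestUnivariateScreen:
    def test_constant_feature_excluded(self):
        X, y = _noise_features(40, 3, 0)
        X["const"] = 5.0
        retained, table = univariate_screen(X, y)
        assert "const" not in retained
        assert table.loc["const", "p_value"] == 1.0
        assert table.loc["const", "degenerate"]

    def test_strong_planted_effect_retained(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 150)
        X = pd.DataFrame({"planted": rng.normal(0, 1, 150) + 2.0 * y})
        retained, _ = univariate_screen(X, y)
        assert retained == ["planted"]

    def test_null_false_positive_rate(self):
        # 58 noise features at alpha=0.05: ~2.9 retained on average
        counts = []
        for seed in range(30):
            X, y = _noise_features(60, 58, 100 + seed)
            retained, _ = univariate_screen(X, y)
            counts.append(len(retained))
        assert 1.5 < np.mean(counts) < 4.5

    def test_minimum_class_size(self):
        X = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ValueError):
            univariate_screen(X, [1, 0, 0, 0, 0])


class TestLassoCV:
    def test_seed_determinism(self):
        X, y = _noise_features(60, 8, 5)
        y = (X["f0"] + np.random.default_rng(5).normal(0, 1, 60) > 0).astype(int)
        a = lasso_cv_select(X, y, repeats=2, seed=11, n_lambdas=30)
        b = lasso_cv_select(X, y, repeats=2, seed=11, n_lambdas=30)
        np.testing.assert_array_equal(a.lambda_grid, b.lambda_grid)
        np.testing.assert_array_equal(a.mean_auc_per_lambda, b.mean_auc_per_lambda)
        assert a.nonzero_features == b.nonzero_features
        c = lasso_cv_select(X, y, repeats=2, seed=12, n_lambdas=30)
        assert not np.array_equal(a.mean_auc_per_lambda, c.mean_auc_per_lambda)

    def test_pure_noise_has_null_cv_auc(self):
        aucs = []
        for seed in range(3):
            X, y = _noise_features(150, 15, 40 + seed)
            rep = lasso_cv_select(X, y, repeats=3, seed=seed, n_lambdas=40)
            aucs.append(rep.best_mean_auc)
        assert np.mean(aucs) <= 0.6

    def test_recovers_planted_feature_among_noise(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(700 + seed)
            y = rng.integers(0, 2, 150)
            X = pd.DataFrame(rng.normal(0, 1, (150, 21)), columns=[f"f{i}" for i in range(21)])
            X["f0"] = X["f0"] + 2.0 * y
            rep = lasso_cv_select(X, y, repeats=1, seed=seed, n_lambdas=30)
            if "f0" in rep.nonzero_features:
                hits += 1
        assert hits / n_seeds > 0.9

    def test_back_transform_identity(self):
        """Raw-scale signature reproduces the standardized-scale scores exactly."""
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 80)
        X = pd.DataFrame(
            {
                "Texture_GLRLM_SRHGE": rng.normal(100, 25, 80) + 30 * y,
                "Texture_GLCM_ASM": rng.normal(0, 0.01, 80),
                "Texture_GLRLM_RV": rng.normal(-5, 2, 80),
            }
        )
        rep = lasso_cv_select(X, y, repeats=2, seed=0, n_lambdas=30)
        sig = build_signature(rep)
        raw_scores = np.asarray(rad_score(sig, X))
        mu, sd = X.values.mean(0), X.values.std(0, ddof=0)
        Xs = (X.values - mu) / np.where(sd > 0, sd, 1.0)
        clf = _l1_logistic(Xs, y, rep.chosen_lambda)
        std_scores = Xs @ clf.coef_.ravel() + clf.intercept_[0]
        np.testing.assert_allclose(raw_scores, std_scores, atol=1e-8)

    def test_monotone_pipeline_subsets(self, small_cohort):
        from radpdl1 import reliability_filter

        table, f1, f2 = small_cohort
        y = table["pdl1_positive"].values
        step1, _ = reliability_filter(f1, f2)
        step2, _ = univariate_screen(f1[step1], y)
        assert set(step2) <= set(step1) <= set(f1.columns)
        if len(step2) >= 2:
            rep = lasso_cv_select(
                f1[step2], y, repeats=1, seed=0, n_lambdas=25, step1_retained=step1
            )
            assert set(rep.nonzero_features) <= set(step2)


class TestBuildSignature:
    def test_intercept_only_signature(self):
        rep = SelectionReport(
            step1_retained=[], step2_retained=[], step2_pvalues=pd.DataFrame(),
            lambda_grid=np.array([1.0]), mean_auc_per_lambda=np.array([0.5]),
            chosen_lambda=1.0, best_mean_auc=0.5, nonzero_features={},
            intercept=-0.4, seed=0,
        )
        sig = build_signature(rep)
        assert rad_score(sig, {}) == pytest.approx(-0.4)
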