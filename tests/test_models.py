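"""Logistic fits, DeLong comparison, bootstrap optimism, model comparison."""

import numpy as np
import pandas as pd
import pytest

from _oracles import delong_p_permutation
from radpdl1 import compare_models, delong_compare, fit_logistic
from radpdl1.models import bootstrap_optimism, chi_square_2x2


def _design_2x2(a, b, c, d):
    """Binary covariate x outcome: (x=1,y=1)=a, (x=1,y=0)=b, (x=0,y=1)=c, (x=0,y=0)=d."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return pd.DataFrame({"x": x}), y.astype(int)


class TestFitLogistic:
    def test_2x2_closed_form_or_and_se(self):
        # table (20,10;10,20): OR = 4, SE(log OR) = sqrt(0.3) = 0.5477
        X, y = _design_2x2(20, 10, 10, 20)
        fit = fit_logistic(X, y)
        row = fit.odds_ratios.loc["x"]
        assert row["OR"] == pytest.approx(4.0, rel=1e-4)
        se = 0.5477225575
        assert row["ci_low"] == pytest.approx(np.exp(np.log(4) - 1.96 * se), rel=1e-3)
        assert row["ci_high"] == pytest.approx(np.exp(np.log(4) + 1.96 * se), rel=1e-3)

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(0, 1, 4000)})
        y = rng.integers(0, 2, 4000)
        fit = fit_logistic(X, y)
        assert fit.odds_ratios.loc["x", "OR"] == pytest.approx(1.0, abs=0.1)
        assert 0.45 <= fit.c_statistic <= 0.55

    def test_constant_covariate_rejected(self):
        X = pd.DataFrame({"x": np.ones(30)})
        with pytest.raises(ValueError):
            fit_logistic(X, np.tile([0, 1], 15))

    def test_perfect_separation_flagged(self):
        X = pd.DataFrame({"x": np.concatenate([np.zeros(15), np.ones(15)])})
        y = X["x"].values.astype(int)
        fit = fit_logistic(X, y)
        assert "possible_separation" in fit.flags
        assert np.isnan(fit.odds_ratios.loc["x", "ci_low"])


class TestDeLong:
    def test_identical_scores(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(0, 1, 40)
        auc1, auc2, delta, p = delong_compare(s, s, y)
        assert delta == 0.0
        assert p == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(0, 1, 40)
        auc1, auc2, delta, _ = delong_compare(s, np.exp(s), y)
        assert auc1 == pytest.approx(auc2, abs=1e-12)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s1 = rng.normal(0, 1, 50) + 0.8 * y
        s2 = rng.normal(0, 1, 50) + 0.3 * y
        a1, a2, delta, p = delong_compare(s1, s2, y)
        b1, b2, delta_b, p_b = delong_compare(s2, s1, y)
        assert delta_b == pytest.approx(-delta, abs=1e-12)
        assert p_b == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_permutation_oracle(self, seed):
        rng = np.random.default_rng(50 + seed)
        n = 30
        y = rng.integers(0, 2, n)
        y[:3] = [0, 1, 0]
        latent = 0.9 * y + rng.normal(0, 1, n)
        s1 = latent + rng.normal(0, 0.8, n)
        s2 = 0.4 * y + rng.normal(0, 1, n)
        _, _, _, p = delong_compare(s1, s2, y)
        p_perm = delong_p_permutation(s1, s2, y, n_perm=2000, seed=seed)
        assert p == pytest.approx(p_perm, abs=0.12)


class TestBootstrapOptimism:
    def _noise_designs(self, n=150, seed=0):
        rng = np.random.default_rng(seed)
        d1 = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["a", "b"])
        d2 = d1.copy()
        d2["c"] = rng.normal(0, 1, n)
        y = rng.integers(0, 2, n)
        return d1, d2, y

    def test_noise_covariates_corrected_to_null(self):
        d1, d2, y = self._noise_designs()
        res = bootstrap_optimism(d1, d2, y, B=100, seed=4)
        assert res.apparent_c2 > res.corrected_c2
        assert 0.4 <= res.corrected_c1 <= 0.62
        assert 0.4 <= res.corrected_c2 <= 0.62
        assert res.optimism1 > 0 and res.optimism2 > 0

    def test_seed_determinism(self):
        d1, d2, y = self._noise_designs(seed=5)
        a = bootstrap_optimism(d1, d2, y, B=30, seed=7)
        b = bootstrap_optimism(d1, d2, y, B=30, seed=7)
        assert a.corrected_c2 == b.corrected_c2
        assert a.delta_c_ci == b.delta_c_ci
        c = bootstrap_optimism(d1, d2, y, B=30, seed=8)
        assert c.corrected_c2 != a.corrected_c2
        assert a.apparent_c2 == c.apparent_c2  # apparent c does not depend on resampling

    def test_strong_predictor_low_optimism(self):
        rng = np.random.default_rng(9)
        n = 200
        y = rng.integers(0, 2, n)
        d1 = pd.DataFrame({"s": 3.0 * y + rng.normal(0, 1, n)})
        d2 = d1.copy()
        d2["noise"] = rng.normal(0, 1, n)
        res = bootstrap_optimism(d1, d2, y, B=60, seed=1)
        assert res.optimism1 < 0.03
        assert res.corrected_c1 > 0.9


class TestCompareModels:
    def _cohort(self, n, radiomic_effect, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        return pd.DataFrame(
            {
                "pdl1_positive": y,
                "age": rng.normal(64, 10, n),
                "sex": rng.choice(["M", "F"], n),
                "smoking": rng.choice(["never", "past", "current"], n),
                "egfr_mutant": rng.integers(0, 2, n),
                "radscore_positive": np.where(
                    rng.random(n) < 0.5 + radiomic_effect * (y - 0.5), 1, 0
                ),
            }
        )

    def test_planted_radiomic_effect_raises_c(self):
        cohort = self._cohort(200, 0.6, seed=2)
        cmp_ = compare_models(cohort, age_cutoff=59, B=50, seed=0)
        assert cmp_.model2.c_statistic > cmp_.model1.c_statistic
        assert cmp_.delta_c == pytest.approx(
            cmp_.model2.c_statistic - cmp_.model1.c_statistic, abs=1e-12
        )
        assert cmp_.bootstrap.corrected_c2 > cmp_.bootstrap.corrected_c1
        assert cmp_.delong_p < 0.05
        assert "radscore_positive" in cmp_.model2.odds_ratios.index
        assert "radscore_positive" not in cmp_.model1.odds_ratios.index

    def test_null_effect_delta_near_zero(self):
        deltas = [
            compare_models(self._cohort(150, 0.0, seed=s), age_cutoff=59, B=20, seed=s).delta_c
            for s in range(4)
        ]
        assert abs(np.mean(deltas)) < 0.06

    def test_report_structure(self):
        cmp_ = compare_models(self._cohort(120, 0.4, seed=3), age_cutoff=59, B=20, seed=1)
        frame = cmp_.summary_frame()
        assert {"model1_OR", "model2_OR", "model2_p_value"} <= set(frame.columns)
        lo, hi = cmp_.bootstrap.delta_c_ci
        assert lo <= hi


def test_chi_square_2x2_paths():
    # balanced independent table -> large p (Yates path)
    assert chi_square_2x2(25, 25, 25, 25) > 0.9
    # sparse table -> Fisher path, still a valid p-value
    p = chi_square_2x2(2, 1, 1, 2)
    assert 0.0 <= p <= 1.0
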