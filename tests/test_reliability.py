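"""ICC, weighted kappa, and the interobserver reliability filter."""

import numpy as np
import pandas as pd
import pytest

from radpdl1 import icc_two_way, reliability_filter, weighted_kappa


class TestICC:
    def test_identical_readers_perfect(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        res = icc_two_way(x, x)
        assert res.icc == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_negative_raw_icc_clamped_to_zero(self):
        r1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r2 = -r1  # strongly anti-correlated
        res = icc_two_way(r1, r2)
        assert res.raw_icc < 0
        assert res.icc == 0.0
        assert res.band == "poor"

    def test_absolute_agreement_penalizes_offset(self):
        rng = np.random.default_rng(0)
        r1 = rng.normal(0, 1, 30)
        r2 = r1 + 5.0
        abs_icc = icc_two_way(r1, r2, model="absolute").icc
        cons_icc = icc_two_way(r1, r2, model="consistency").icc
        assert abs_icc < cons_icc
        assert cons_icc == pytest.approx(1.0)

    def test_symmetry_and_shift_invariance(self):
        rng = np.random.default_rng(1)
        r1 = rng.normal(0, 1, 25)
        r2 = r1 + rng.normal(0, 0.3, 25)
        a = icc_two_way(r1, r2).raw_icc
        assert icc_two_way(r2, r1).raw_icc == pytest.approx(a, rel=1e-12)
        assert icc_two_way(r1 + 10, r2 + 10).raw_icc == pytest.approx(a, rel=1e-9)

    def test_zero_total_variance_flagged(self):
        res = icc_two_way([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.icc == 1.0
        assert "zero_total_variance" in res.flags

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        r1 = rng.normal(50, 10, 20)
        r2 = r1 + rng.normal(0, 3, 20) + 1.0
        mine = icc_two_way(r1, r2).raw_icc
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 2),
                "rater": np.tile(["a", "b"], 20),
                "score": np.column_stack([r1, r2]).ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert mine == pytest.approx(icc2, abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc_two_way([1.0, 2.0], [1.0, 2.0])  # n < 3
        with pytest.raises(ValueError):
            icc_two_way([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


class TestWeightedKappa:
    def test_perfect_agreement(self):
        k, band = weighted_kappa([1, 2, 3, 2, 1], [1, 2, 3, 2, 1], n_categories=3)
        assert k == pytest.approx(1.0)
        assert band == "excellent"

    def test_complete_disagreement_two_categories(self):
        # symmetric marginals, all off-diagonal -> kappa = -1
        r1 = [1, 1, 2, 2]
        r2 = [2, 2, 1, 1]
        k, _ = weighted_kappa(r1, r2, n_categories=2)
        assert k == pytest.approx(-1.0)

    def test_independent_readers_near_zero(self):
        rng = np.random.default_rng(3)
        r1 = rng.integers(1, 5, 4000)
        r2 = rng.integers(1, 5, 4000)
        k, _ = weighted_kappa(r1, r2, n_categories=4)
        assert abs(k) < 0.05

    def test_single_category_undefined(self):
        with pytest.raises(ValueError):
            weighted_kappa([2, 2, 2], [2, 2, 2], n_categories=3)

    def test_codes_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa([0, 1], [1, 1], n_categories=2)


class TestReliabilityFilter:
    def _tables(self, n=20, p=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        f1 = pd.DataFrame(rng.normal(0, 1, (n, p)), columns=[f"f{i}" for i in range(p)])
        f2 = f1 + rng.normal(0, noise, (n, p))
        return f1, f2

    def test_identical_readers_retain_everything(self):
        f1, f2 = self._tables(noise=0.0)
        retained, report = reliability_filter(f1, f2)
        assert retained == list(f1.columns)
        np.testing.assert_allclose(report["icc"], 1.0, atol=1e-12)

    def test_noise_feature_dropped(self):
        f1, f2 = self._tables(noise=0.05, seed=1)
        rng = np.random.default_rng(2)
        f2["f3"] = rng.normal(0, 1, len(f2))  # reader 2 disagrees completely
        retained, report = reliability_filter(f1, f2)
        assert "f3" not in retained
        assert report.loc["f3", "icc"] < 0.75
        assert set(retained) <= set(f1.columns)

    def test_threshold_one_retains_nothing_unless_exact(self):
        f1, f2 = self._tables(noise=0.01, seed=3)
        retained, _ = reliability_filter(f1, f2, threshold=1.0)
        assert retained == []
        retained_exact, _ = reliability_filter(f1, f1.copy(), threshold=1.0)
        assert retained_exact == []  # icc == 1 is not strictly > 1

    def test_column_mismatch_rejected(self):
        f1, f2 = self._tables()
        with pytest.raises(ValueError):
            reliability_filter(f1, f2.rename(columns={"f0": "g0"}))

    def test_full_catalogue_retained_on_default_cohort(self, small_cohort):
        _, f1, f2 = small_cohort
        retained, report = reliability_filter(f1, f2)
        # phantom readers agree closely: the large majority of the 58 survive
        assert len(retained) >= 50
        assert len(report) == 58
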