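"""Discretization, GLCM and GLRLM: worked examples, oracle equivalence, invariants."""

import numpy as np
import pytest

from _oracles import glcm_features_bruteforce, glrlm_features_bruteforce, runs_bruteforce
from conftest import random_discretized
from radpdl1 import VolumeWithMask
from radpdl1.features import (
    OFFSETS_3D,
    discretize,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    run_length_matrix,
)


def _voi_1d(values, spacing=(1, 1, 1)):
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return VolumeWithMask(arr, spacing, np.ones(arr.shape, bool))


class TestDiscretize:
    def test_two_values_two_levels(self):
        d = discretize(_voi_1d([0.0, 100.0]), G=2)
        assert list(d.levels.ravel()) == [1, 2]
        assert not d.degenerate

    def test_midpoint_falls_in_upper_bin(self):
        d = discretize(_voi_1d([0.0, 50.0, 100.0]), G=2)
        assert list(d.levels.ravel()) == [1, 2, 2]

    def test_constant_voi_degenerate(self):
        d = discretize(_voi_1d([7.0, 7.0, 7.0]), G=8)
        assert d.degenerate
        assert set(d.levels.ravel()) == {1}

    def test_levels_cover_full_range(self):
        d = random_discretized(0, G=6)
        inside = d.levels[d.mask]
        assert inside.min() >= 1 and inside.max() <= 6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discretize(_voi_1d([1.0, 2.0]), G=1)


class TestGLCM:
    def test_constant_texture(self):
        d = discretize(_voi_1d([5.0] * 8), G=4)
        vals, flags = glcm_features(d)
        assert vals["Texture_GLCM_ASM"] == pytest.approx(1.0)
        assert vals["Texture_GLCM_Contrast"] == 0.0
        assert vals["Texture_GLCM_Entropy"] == 0.0
        assert "glcm_degenerate" in flags

    def test_alternating_sequence_hand_computed(self):
        # 1,2,1,2 along one axis: p(1,2)=p(2,1)=0.5
        d = discretize(_voi_1d([0.0, 100.0, 0.0, 100.0]), G=2)
        vals, _ = glcm_features(d, offsets=[(1, 0, 0)])
        assert vals["Texture_GLCM_ASM"] == pytest.approx(0.5)
        assert vals["Texture_GLCM_Contrast"] == pytest.approx(1.0)
        assert vals["Texture_GLCM_Correlation"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence(self, seed):
        d = random_discretized(seed, shape=(5, 5, 5), G=4)
        vals, _ = glcm_features(d)
        oracle = glcm_features_bruteforce(d.levels, d.G)
        for name, expected in oracle.items():
            assert vals[name] == pytest.approx(expected, abs=1e-10), name

    @pytest.mark.parametrize("seed", range(8))
    def test_matrix_normalized_and_symmetric(self, seed):
        d = random_discretized(100 + seed, shape=(6, 6, 6), G=5)
        p = glcm_matrix(d)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(p, p.T, atol=1e-15)


class TestGLRLM:
    def test_single_run_hand_computed(self):
        d = discretize(_voi_1d([5.0, 5.0, 5.0]), G=2)
        d.levels[:] = np.where(d.mask, 1, 0)  # force one level without degenerate flag
        vals = {}
        r = run_length_matrix(d, (1, 0, 0))
        assert r.shape[1] == 3 and r[0, 2] == 1 and r.sum() == 1
        from radpdl1.features.texture import _glrlm_single

        vals = _glrlm_single(r, 3)
        assert vals["Texture_GLRLM_SRE"] == pytest.approx(1.0 / 9.0)
        assert vals["Texture_GLRLM_LRE"] == pytest.approx(9.0)
        assert vals["Texture_GLRLM_RP"] == pytest.approx(1.0 / 3.0)
        assert vals["Texture_GLRLM_RV"] == pytest.approx(0.0)
        assert vals["Texture_GLRLM_RE"] == pytest.approx(0.0)

    def test_two_runs_hand_computed(self):
        # levels 1,1,2 -> runs {(1,2),(2,1)}
        d = discretize(_voi_1d([0.0, 0.0, 100.0]), G=2)
        from radpdl1.features.texture import _glrlm_single

        vals = _glrlm_single(run_length_matrix(d, (1, 0, 0)), 3)
        assert vals["Texture_GLRLM_SRE"] == pytest.approx(0.625)
        assert vals["Texture_GLRLM_LRE"] == pytest.approx(2.5)
        assert vals["Texture_GLRLM_RP"] == pytest.approx(2.0 / 3.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence(self, seed):
        d = random_discretized(200 + seed, shape=(5, 5, 5), G=4)
        vals, _ = glrlm_features(d)
        oracle = glrlm_features_bruteforce(d.levels, d.G)
        for name, expected in oracle.items():
            assert vals[name] == pytest.approx(expected, abs=1e-10), name

    @pytest.mark.parametrize("seed", range(8))
    def test_run_conservation(self, seed):
        """For every direction, total run length equals the voxel count."""
        d = random_discretized(300 + seed, shape=(6, 6, 6), G=5)
        n_voxels = int((d.levels > 0).sum())
        for off in OFFSETS_3D:
            r = run_length_matrix(d, off)
            lengths = np.arange(1, r.shape[1] + 1)
            assert (r * lengths).sum() == pytest.approx(n_voxels)
            # and agrees with the walking oracle run-by-run
            runs = runs_bruteforce(d.levels, off)
            assert r.sum() == len(runs)
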