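import math

import numpy as np
import pytest

from hippotex import (
    DirectionSet,
    QuantizedRoi,
    Volume,
    circular_mask,
    directions,
    extract_features,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    histogram_features,
    spherical_mask,
)
from hippotex.errors import DegenerateRoiError, ParameterError
from hippotex.volume_io import FEATURE_NAMES

from ._oracles import brute_glcm, brute_glcm_features, brute_glrlm
from .conftest import random_quantized


def qroi_from(levels, n_levels, valid=None):
    levels = np.asarray(levels)
    if valid is None:
        valid = levels > 0
    return QuantizedRoi(levels=levels, valid=valid, n_levels=n_levels)


SINGLE_Z = DirectionSet(offsets=((0, 0, 1),), weights=(1.0,))


class TestDirections:
    def test_2d_has_four_in_plane_offsets(self):
        d = directions("2d", slice_axis=0)
        assert len(d.offsets) == 4
        assert all(off[0] == 0 for off in d.offsets)
        assert d.weights == (0.25, 0.25, 0.25, 0.25)

    def test_2d_offsets_cover_four_angles(self):
        d = directions("2d", slice_axis=2)
        planar = {(off[0], off[1]) for off in d.offsets}
        assert planar == {(0, 1), (1, 1), (1, 0), (1, -1)}

    def test_3d_has_thirteen_offsets_by_step_length(self):
        d = directions("3d")
        norms = sorted(math.sqrt(sum(c * c for c in off)) for off in d.offsets)
        assert len(d.offsets) == 13
        assert norms.count(1.0) == 3  # axis
        assert sum(1 for n in norms if abs(n - math.sqrt(2)) < 1e-12) == 6  # face diag
        assert sum(1 for n in norms if abs(n - math.sqrt(3)) < 1e-12) == 4  # space diag

    def test_3d_inverse_length_weights(self):
        d = directions("3d")
        by_norm = {}
        for off, w in zip(d.offsets, d.weights):
            by_norm.setdefault(round(sum(c * c for c in off)), w)
        # axis : face-diagonal : space-diagonal weights = 1 : 1/sqrt2 : 1/sqrt3
        assert by_norm[2] / by_norm[1] == pytest.approx(1 / math.sqrt(2))
        assert by_norm[3] / by_norm[1] == pytest.approx(1 / math.sqrt(3))
        assert sum(d.weights) == pytest.approx(1.0, abs=1e-12)
        norm = 3 + 6 / math.sqrt(2) + 4 / math.sqrt(3)
        assert by_norm[1] == pytest.approx(1 / norm)

    def test_no_antipodal_pairs(self):
        for mode in ("2d", "3d"):
            offs = set(directions(mode).offsets)
            assert not any(tuple(-c for c in o) in offs for o in offs)

    def test_bad_mode_rejected(self):
        with pytest.raises(ParameterError):
            directions("4d")


class TestGlcm:
    def test_two_cell_strip_single_offset(self):
        q = qroi_from([[[1, 2]]], 2)
        p = glcm(q, SINGLE_Z).p
        assert p[0, 1] == 0.5 and p[1, 0] == 0.5
        assert p[0, 0] == 0 and p[1, 1] == 0

    def test_constant_roi_concentrates_at_diagonal(self):
        q = qroi_from(np.full((1, 4, 4), 5), 6)
        for dirs in (SINGLE_Z, directions("2d", 0), directions("3d")):
            p = glcm(q, dirs).p
            assert p[4, 4] == 1.0 and p.sum() == 1.0

    def test_checkerboard_antidiagonal(self):
        board = 1 + (np.add.outer(np.arange(3), np.arange(3)) % 2)
        q = qroi_from(board[None, :, :], 2)
        dirs = DirectionSet(offsets=((0, 0, 1), (0, 1, 0)), weights=(0.5, 0.5))
        p = glcm(q, dirs).p
        assert p[0, 1] == pytest.approx(0.5) and p[1, 0] == pytest.approx(0.5)
        assert p[0, 0] == 0 and p[1, 1] == 0

    def test_symmetric_and_normalized(self, rng):
        for _ in range(10):
            q = random_quantized(rng, (5, 5, 5), 4)
            p = glcm(q, directions("3d")).p
            assert np.allclose(p, p.T)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p >= 0)

    def test_no_pairs_raises(self):
        valid = np.zeros((3, 3, 3), dtype=bool)
        valid[0, 0, 0] = valid[2, 2, 1] = True  # no offset links these
        levels = valid.astype(int)
        q = QuantizedRoi(levels=levels, valid=valid, n_levels=2)
        with pytest.raises(DegenerateRoiError):
            glcm(q, SINGLE_Z)

    def test_matches_brute_force_enumeration(self, rng):
        for trial in range(25):
            mode = "2d" if trial % 2 else "3d"
            shape = (1, 6, 6) if mode == "2d" else (5, 5, 5)
            dirs = directions(mode, slice_axis=0)
            q = random_quantized(rng, shape, 4)
            p = glcm(q, dirs).p
            ref = brute_glcm(q.levels, q.valid, dirs.offsets, dirs.weights, 4)
            assert np.allclose(p, ref, atol=1e-12)


class TestGlcmFeatures:
    def test_constant_roi_closed_forms(self):
        q = qroi_from(np.full((1, 4, 4), 5), 6)
        f = glcm_features(glcm(q, directions("2d", 0)))
        assert f["Energy"] == 1.0
        assert f["Contrast"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Homogeneity"] == 1.0
        assert f["Dissimilarity"] == 0.0
        assert f["Autocorrelation"] == 25.0
        assert f["Sum Average"] == 10.0
        assert f["Variance"] == 0.0
        assert math.isnan(f["Correlation"])

    def test_checkerboard_closed_forms(self):
        from hippotex.texture_features import Glcm

        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(Glcm(p=p, n_levels=2))
        assert f["Contrast"] == 1.0
        assert f["Correlation"] == pytest.approx(-1.0)
        assert f["Energy"] == 0.5
        assert f["Entropy"] == pytest.approx(1.0)
        assert f["Homogeneity"] == pytest.approx(0.5)
        assert f["Autocorrelation"] == pytest.approx(2.0)
        assert f["Sum Average"] == pytest.approx(3.0)

    def test_matches_brute_force_evaluator(self, rng):
        from hippotex.texture_features import Glcm

        for _ in range(20):
            c = rng.random((5, 5))
            p = c + c.T
            p /= p.sum()
            ours = glcm_features(Glcm(p=p, n_levels=5))
            ref = brute_glcm_features(p)
            for name, value in ref.items():
                assert ours[name] == pytest.approx(value, abs=1e-12), name

    def test_invariant_ranges(self, rng):
        for _ in range(10):
            q = random_quantized(rng, (5, 5, 5), 4)
            f = glcm_features(glcm(q, directions("3d")))
            assert 0 < f["Energy"] <= 1
            assert f["Entropy"] >= 0
            assert 0 < f["Homogeneity"] <= 1
            if not math.isnan(f["Correlation"]):
                assert -1 - 1e-12 <= f["Correlation"] <= 1 + 1e-12


class TestGlrlm:
    def test_single_run(self):
        g = glrlm(qroi_from([[[1, 1, 1]]], 1), SINGLE_Z)
        assert g.r[0, 2] == 1.0 and g.r.sum() == 1.0
        assert g.n_runs == 1.0 and g.n_voxels == 3

    def test_two_runs(self):
        g = glrlm(qroi_from([[[1, 2, 2]]], 2), SINGLE_Z)
        assert g.r[0, 0] == 1.0 and g.r[1, 1] == 1.0 and g.n_runs == 2.0

    def test_run_broken_by_hole(self):
        levels = np.array([[[1, 1, 1, 1, 1]]])
        valid = np.array([[[True, True, False, True, True]]])
        g = glrlm(QuantizedRoi(levels * valid, valid, 1), SINGLE_Z)
        assert g.r[0, 1] == 2.0  # two runs of length 2, never bridged
        assert g.n_voxels == 4

    @pytest.mark.parametrize("n,axis", [(3, 0), (4, 1), (5, 2)])
    def test_constant_cube_axis_runs(self, n, axis):
        off = [0, 0, 0]
        off[axis] = 1
        dirs = DirectionSet(offsets=(tuple(off),), weights=(1.0,))
        g = glrlm(qroi_from(np.full((n, n, n), 2), 3), dirs)
        assert g.r[1, n - 1] == n ** 2
        assert g.r.sum() == n ** 2

    def test_matches_brute_force_enumeration(self, rng):
        for trial in range(25):
            mode = "2d" if trial % 2 else "3d"
            shape = (1, 6, 6) if mode == "2d" else (5, 5, 5)
            dirs = directions(mode, slice_axis=0)
            q = random_quantized(rng, shape, 4)
            r = glrlm(q, dirs).r
            ref = brute_glrlm(q.levels, q.valid, dirs.offsets, dirs.weights, 4)
            assert np.allclose(r, ref, atol=1e-12)


class TestGlrlmFeatures:
    def _features_of(self, r, n_voxels):
        from hippotex.texture_features import Glrlm

        r = np.asarray(r, dtype=float)
        return glrlm_features(
            Glrlm(r=r, n_runs=float(r.sum()), n_voxels=n_voxels, n_levels=r.shape[0])
        )

    def test_single_run_closed_forms(self):
        r = np.zeros((1, 3))
        r[0, 2] = 1.0
        f = self._features_of(r, 3)
        expected = {
            "SRE": 1 / 9, "LRE": 9.0, "GLN": 1.0, "RLN": 1.0, "RP": 1 / 3,
            "LGRE": 1.0, "HGRE": 1.0, "SRLGE": 1 / 9, "SRHGE": 1 / 9,
            "LRLGE": 9.0, "LRHGE": 9.0, "GLV": 0.0, "RLV": 0.0,
        }
        for name, value in expected.items():
            assert f[name] == pytest.approx(value), name

    def test_two_run_closed_forms(self):
        r = np.zeros((2, 2))
        r[0, 0] = r[1, 1] = 1.0
        f = self._features_of(r, 3)
        assert f["SRE"] == pytest.approx(0.625)
        assert f["RP"] == pytest.approx(2 / 3)
        assert f["GLV"] == pytest.approx(0.25)
        assert f["RLV"] == pytest.approx(0.25)

    def test_all_runs_length_one(self):
        board = 1 + (np.add.outer(np.arange(4), np.arange(4)) % 2)
        dirs = DirectionSet(offsets=((0, 0, 1), (0, 1, 0)), weights=(0.5, 0.5))
        f = glrlm_features(glrlm(qroi_from(board[None, :, :], 2), dirs))
        assert f["SRE"] == 1.0 and f["LRE"] == 1.0 and f["RP"] == 1.0


class TestHistogramFeatures:
    def test_constant_roi(self):
        f = histogram_features(qroi_from([[[3, 3, 3]]], 4))
        assert f["Global Variance"] == 0.0
        assert math.isnan(f["Skewness"]) and math.isnan(f["Kurtosis"])

    def test_hand_computed_moments(self):
        f = histogram_features(qroi_from([[[1, 2, 2, 3]]], 3))
        assert f["Global Variance"] == pytest.approx(0.5)
        assert f["Skewness"] == pytest.approx(0.0)
        assert f["Kurtosis"] == pytest.approx(2.0)

    def test_uniform_levels_match_closed_forms(self, rng):
        levels = rng.integers(1, 65, (1, 1, 200000))
        f = histogram_features(qroi_from(levels, 64))
        assert f["Skewness"] == pytest.approx(0.0, abs=0.05)
        assert f["Kurtosis"] == pytest.approx(1.8, abs=0.05)


class TestExtractFeatures:
    def test_panel_has_25_named_features(self, noise_volume, center_sphere):
        f = extract_features(noise_volume, center_sphere)
        assert list(f) == list(FEATURE_NAMES)
        assert len(f) == 25

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_in_plane_rotation_invariance(self, rng, k):
        data = rng.normal(1000, 100, (15, 15, 15))
        mask = circular_mask((15, 15, 15), (7, 7, 7), 5, slice_axis=0)
        base = extract_features(Volume(data), mask)
        rotated = extract_features(Volume(np.rot90(data, k, axes=(1, 2))), mask)
        for name in FEATURE_NAMES:
            assert rotated[name] == pytest.approx(base[name], abs=1e-9), name

    @pytest.mark.parametrize("axis", [1, 2])
    def test_mirror_flip_invariance(self, rng, axis):
        data = rng.normal(1000, 100, (15, 15, 15))
        mask = circular_mask((15, 15, 15), (7, 7, 7), 5, slice_axis=0)
        base = extract_features(Volume(data), mask)
        flipped = extract_features(Volume(np.flip(data, axis=axis)), mask)
        for name in FEATURE_NAMES:
            assert flipped[name] == pytest.approx(base[name], abs=1e-9), name

    @pytest.mark.parametrize("perm", [(1, 0, 2), (2, 1, 0), (1, 2, 0), (2, 0, 1)])
    def test_axis_permutation_invariance_3d(self, rng, perm):
        data = rng.normal(1000, 100, (15, 15, 15))
        mask = spherical_mask((15, 15, 15), (7, 7, 7), 5)
        base = extract_features(Volume(data), mask)
        permuted = extract_features(Volume(data.transpose(perm)), mask)
        for name in FEATURE_NAMES:
            assert permuted[name] == pytest.approx(base[name], abs=1e-9), name

    def test_affine_intensity_invariance_end_to_end(self, rng):
        data = rng.normal(1000, 100, (15, 15, 15))
        mask = spherical_mask((15, 15, 15), (7, 7, 7), 5)
        base = extract_features(Volume(data), mask)
        scaled = extract_features(Volume(2.5 * data + 300.0), mask)
        for name in FEATURE_NAMES:
            assert scaled[name] == pytest.approx(base[name], abs=1e-9), name

    def test_radii_give_different_but_complete_vectors(self, noise_volume):
        f3 = extract_features(noise_volume, spherical_mask((21, 21, 21), (10, 10, 10), 3))
        f5 = extract_features(noise_volume, spherical_mask((21, 21, 21), (10, 10, 10), 5))
        assert len(f3) == len(f5) == 25
        assert any(f3[n] != f5[n] for n in FEATURE_NAMES)

    def test_constant_volume_degenerate_panel(self):
        vol = Volume(np.full((15, 15, 15), 500.0))
        f = extract_features(vol, spherical_mask((15, 15, 15), (7, 7, 7), 4))
        assert f["Energy"] == 1.0 and f["Contrast"] == 0.0
        assert math.isnan(f["Correlation"]) and math.isnan(f["Skewness"])
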