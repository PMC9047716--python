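"""Texture-matrix features: hand-enumerated examples, normalization and
symmetry contracts, rotation consistency, and the planted-contrast
monotonicity the phantoms rely on."""

import numpy as np
import pytest

from conftest import make_blob_sample, make_strip_sample
from radiomath.features import (
    discretize,
    extract_roi,
    gldm_matrix,
    glcm_features,
    glcm_matrices,
    glrlm_matrices,
    glszm_features,
    glszm_matrix,
    roi_sample,
)
from radiomath.features.base import DIRECTIONS_3D
from radiomath.features.gldm import dependence_counts


def in_strip_direction_index(axis=2):
    return DIRECTIONS_3D.index(tuple(1 if a == axis else 0 for a in range(3)))


class TestGlcm:
    def test_constant_roi_forced_values(self):
        f = glcm_features(discretize(make_strip_sample([5.0] * 8)))
        assert f["glcm_JointEnergy"] == 1.0
        assert f["glcm_JointEntropy"] == 0.0
        assert f["glcm_Contrast"] == 0.0
        assert f["glcm_MaximumProbability"] == 1.0
        assert f["glcm_Correlation"] == 1.0

    def test_alternating_strip_hand_enumeration(self):
        """[1,2,1,2] with bin width collapsing to two levels: the only
        direction with pairs gives P(1,2)=P(2,1)=0.5 and Contrast 1."""
        disc = discretize(make_strip_sample([0.0, 25.0, 0.0, 25.0]))
        mats = glcm_matrices(disc)
        assert len(mats) == 1  # only the in-strip direction has pairs
        assert np.allclose(mats[0], [[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(disc)
        assert f["glcm_Contrast"] == pytest.approx(1.0)

    def test_matrices_normalized_and_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            disc = discretize(make_blob_sample(rng))
            for m in glcm_matrices(disc):
                assert m.sum() == pytest.approx(1.0, abs=1e-9)
                assert np.allclose(m, m.T, atol=1e-12)


class TestGlrlm:
    def test_constant_strip_single_run(self):
        disc = discretize(make_strip_sample([7.0] * 4))
        P = glrlm_matrices(disc)[in_strip_direction_index()]
        assert P.shape == (1, 4)
        assert P[0].tolist() == [0, 0, 0, 1]  # one run of length 4
        # LongRunEmphasis of that matrix: sum p(i,j) j^2 = 16
        assert (P * np.arange(1, 5) ** 2).sum() / P.sum() == 16
        # RunPercentage in-strip: 1 run / 4 voxels
        assert P.sum() / 4 == 0.25

    def test_alternating_strip_unit_runs(self):
        disc = discretize(make_strip_sample([0.0, 25.0, 0.0, 25.0]))
        P = glrlm_matrices(disc)[in_strip_direction_index()]
        assert P.shape == (2, 1)
        assert P[:, 0].tolist() == [2, 2]  # four runs of length 1
        stats = (P / np.arange(1, 2) ** 2).sum() / P.sum()
        assert stats == 1.0  # Short and LongRunEmphasis both 1

    def test_off_axis_directions_of_strip_see_single_voxel_runs(self):
        disc = discretize(make_strip_sample([7.0] * 4))
        for d, P in zip(DIRECTIONS_3D, glrlm_matrices(disc)):
            if d == (0, 0, 1):
                continue
            assert P.shape[1] == 1 and P.sum() == 4


class TestGlszm:
    def test_constant_patch_single_zone(self):
        vol = np.full((2, 2, 1), 9.0)
        labels = np.ones((2, 2, 1), np.int16)
        disc = discretize(roi_sample(vol, labels, 1, (1, 1, 1)))
        P = glszm_matrix(disc)
        assert P.shape == (1, 4)
        assert P[0].tolist() == [0, 0, 0, 1]
        f = glszm_features(disc)
        assert f["glszm_ZonePercentage"] == 0.25

    def test_all_distinct_levels_give_unit_zones(self):
        disc = discretize(make_strip_sample([0.0, 30.0, 60.0, 90.0]))
        f = glszm_features(disc)
        assert f["glszm_SmallAreaEmphasis"] == 1.0
        assert f["glszm_ZonePercentage"] == 1.0

    def test_diagonal_zones_merge_under_26_connectivity(self):
        vol = np.array([[[0.0, 30.0], [30.0, 0.0]]]).reshape(1, 2, 2)
        labels = np.ones((1, 2, 2), np.int16)
        P = glszm_matrix(discretize(roi_sample(vol, labels, 1, (1, 1, 1))))
        # both levels form one diagonal 2-voxel zone each
        assert P[:, 1].tolist() == [1, 1]


class TestGldm:
    def test_constant_patch_neighbour_counts(self):
        vol = np.full((3, 3, 1), 4.0)
        labels = np.ones((3, 3, 1), np.int16)
        disc = discretize(roi_sample(vol, labels, 1, (1, 1, 1)))
        dep = dependence_counts(disc).ravel()
        assert sorted(dep.tolist()) == [3, 3, 3, 3, 5, 5, 5, 5, 8]
        P = gldm_matrix(disc)
        # dependence size = neighbours + centre: 4 corners, 4 edges, 1 centre
        assert P[0, 3] == 4 and P[0, 5] == 4 and P[0, 8] == 1
        assert P.sum() == 9


def test_rotation_consistency_of_direction_averaged_features():
    """90-degree axis rotations permute the 13 directions, leaving every
    direction-averaged texture feature unchanged."""
    rng = np.random.default_rng(12)
    s = make_blob_sample(rng, spacing=(1.0, 1.0, 1.0))
    shape = (12, 12, 12)
    vol = np.zeros(shape)
    labels = np.zeros(shape, np.int16)
    vol[s.coords[:, 0], s.coords[:, 1], s.coords[:, 2]] = s.intensities
    labels[s.coords[:, 0], s.coords[:, 1], s.coords[:, 2]] = 1

    base = extract_roi(roi_sample(vol, labels, 1, (1, 1, 1)))
    for axes in [(0, 1), (0, 2), (1, 2)]:
        rot = extract_roi(
            roi_sample(np.rot90(vol, axes=axes), np.rot90(labels, axes=axes), 1, (1, 1, 1))
        )
        for name, value in base.items():
            if name.startswith(("glcm_", "glrlm_", "glszm_", "gldm_", "firstorder_")):
                assert rot[name] == pytest.approx(value, rel=1e-9, abs=1e-12), name


def test_contrast_increases_with_planted_noise_sd():
    """GLCM Contrast must respond monotonically (in expectation) to the
    noise SD the phantom plants — the handle the texture-contrast signal
    rides on."""
    from scipy.ndimage import gaussian_filter

    wins = 0
    for seed in range(6):
        rng = np.random.default_rng(seed)
        field = gaussian_filter(rng.standard_normal((16, 16, 16)), 0.8)
        field /= field.std()
        labels = np.ones((16, 16, 16), np.int16)
        lo = extract_roi(roi_sample(300 + 40 * field, labels, 1, (1, 1, 1)))
        hi = extract_roi(roi_sample(300 + 120 * field, labels, 1, (1, 1, 1)))
        wins += hi["glcm_Contrast"] > lo["glcm_Contrast"]
    assert wins == 6
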