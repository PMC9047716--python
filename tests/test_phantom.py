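"""Phantom generator: geometry, planted effects, null behaviour, fixtures."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from radiomath import (
    PhantomSpec,
    RoiGeometry,
    SignalEffect,
    default_phantom_spec,
    generate_phantom,
)
from radiomath.io import read_nifti, write_fixture_set


def test_label_volume_has_exactly_k_foreground_labels():
    spec = default_phantom_spec(n_rois=3, shape=(24, 24, 24))
    _, labels = generate_phantom({}, spec, np.random.default_rng(0))
    present = sorted(np.unique(labels))
    assert present == [0, 1, 2, 3]
    # expected ellipsoid voxel count within a voxelization margin
    expected = 4.0 / 3.0 * np.pi * np.prod(spec.rois[0].radii)
    for k in (1, 2, 3):
        assert abs((labels == k).sum() - expected) / expected < 0.25


def test_overlapping_rois_rejected():
    spec = PhantomSpec(
        shape=(20, 20, 20),
        rois=[
            RoiGeometry(center=(10, 10, 10), radii=(5, 5, 5)),
            RoiGeometry(center=(12, 10, 10), radii=(5, 5, 5)),
        ],
    )
    with pytest.raises(ValueError, match="overlap"):
        spec.validate()


def test_signal_plan_with_unknown_roi_rejected():
    spec = default_phantom_spec(
        n_rois=2, shape=(20, 20, 20),
        signal_plan=[SignalEffect(5, "texture-contrast", 1.0)],
    )
    with pytest.raises(ValueError, match="1..K"):
        spec.validate()


def test_texture_contrast_effect_scales_noise_sd():
    """beta = 2 between scores 0 and 1 should triple the ROI sample SD."""
    spec = default_phantom_spec(
        n_rois=1, shape=(48, 48, 48), radius=14,
        signal_plan=[SignalEffect(1, "texture-contrast", 2.0, "mf")],
    )
    i0, l0 = generate_phantom({"mf_norm": 0.0}, spec, np.random.default_rng(1))
    i1, l1 = generate_phantom({"mf_norm": 1.0}, spec, np.random.default_rng(2))
    ratio = i1[l1 == 1].std() / i0[l0 == 1].std()
    assert ratio == pytest.approx(3.0, rel=0.2)


def test_volume_effect_scales_roi_volume():
    spec = default_phantom_spec(
        n_rois=1, shape=(48, 48, 48), radius=10,
        signal_plan=[SignalEffect(1, "volume", 1.0, "mf")],
    )
    v0 = (generate_phantom({"mf_norm": 0.0}, spec, np.random.default_rng(3))[1] == 1).sum()
    v1 = (generate_phantom({"mf_norm": 1.0}, spec, np.random.default_rng(4))[1] == 1).sum()
    assert v1 / v0 == pytest.approx(2.0, rel=0.1)


def test_null_phantoms_statistically_identical_across_subjects():
    """With all effects zero, ROI intensity samples of high- and
    low-scoring subjects are exchangeable: a two-sample KS test rejects
    at its nominal rate only.  Unsmoothed noise keeps voxels independent
    so the KS calibration applies exactly."""
    spec = default_phantom_spec(
        n_rois=1, shape=(16, 16, 16), radius=5, smooth_sigma=0.0
    )
    rejections = 0
    n_pairs = 60
    for k in range(n_pairs):
        ia, la = generate_phantom({"mf_norm": 0.05}, spec, np.random.default_rng(2 * k))
        ib, lb = generate_phantom({"mf_norm": 0.95}, spec, np.random.default_rng(2 * k + 1))
        if ks_2samp(ia[la == 1], ib[lb == 1]).pvalue < 0.05:
            rejections += 1
    # 95% binomial upper bound around rate 0.05 at n=60 is ~8
    assert rejections <= 8


def test_phantom_deterministic_under_seed():
    spec = default_phantom_spec(n_rois=2, shape=(20, 20, 20))
    a = generate_phantom({}, spec, np.random.default_rng(5))
    b = generate_phantom({}, spec, np.random.default_rng(5))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestFixtureSet:
    def _write(self, tmp_path, small_cohort, spec, n=3):
        cohort = small_cohort.head(n)
        rng = np.random.default_rng(0)
        phantoms = [generate_phantom(row, spec, rng) for _, row in cohort.iterrows()]
        return cohort, phantoms, write_fixture_set(cohort, phantoms, tmp_path, spec, seed=0)

    def test_file_count_and_round_trip(self, tmp_path, small_cohort, small_phantom_spec):
        cohort, phantoms, manifest = self._write(tmp_path, small_cohort, small_phantom_spec)
        assert len(manifest["files"]) == 2 * 3 + 1  # 6 NIfTI + cohort.csv
        sid = cohort.iloc[0]["subject_id"]
        img, _ = read_nifti(tmp_path / f"{sid}_T1w.nii.gz")
        lab, _ = read_nifti(tmp_path / f"{sid}_labels.nii.gz")
        assert np.array_equal(img, phantoms[0][0])
        assert np.array_equal(lab, phantoms[0][1])
        assert lab.dtype.kind == "i"

    def test_manifest_hash_stable_and_guarding(self, tmp_path, small_cohort, small_phantom_spec):
        _, _, m1 = self._write(tmp_path, small_cohort, small_phantom_spec)
        _, _, m2 = self._write(tmp_path, small_cohort, small_phantom_spec)
        assert m1["spec_hash"] == m2["spec_hash"]
        other = default_phantom_spec(n_rois=2, shape=(20, 20, 20))
        with pytest.raises(FileExistsError, match="different phantom spec"):
            self._write(tmp_path, small_cohort, other)
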