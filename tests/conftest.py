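"""Shared fixtures: small ROIs, phantoms, cohorts, and feature tables.

Everything is generated programmatically at test time; the suite ships
no binary data.  Problem sizes are desk-scale (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from radiomath import (
    default_cohort_spec,
    default_phantom_spec,
    extract_all,
    generate_cohort,
    generate_phantom,
    normalize_scores,
)
from radiomath.features import roi_sample


def make_blob_sample(rng, shape=(10, 10, 10), max_steps=100, spacing=None):
    """Random-walk blob ROI with smooth noisy intensities."""
    vol = 300.0 + 300.0 * gaussian_filter(rng.standard_normal(shape), 0.8)
    mask = np.zeros(shape, dtype=bool)
    p = np.array(shape) // 2
    for _ in range(int(rng.integers(20, max_steps))):
        mask[tuple(p)] = True
        p = np.clip(p + rng.integers(-1, 2, 3), 0, np.array(shape) - 1)
    if spacing is None:
        spacing = rng.uniform(0.8, 1.5, 3)
    return roi_sample(vol, mask.astype(np.int16), 1, spacing)


def make_strip_sample(values, axis=2):
    """1 x 1 x n strip ROI with the given intensities along ``axis``."""
    n = len(values)
    shape = [1, 1, 1]
    shape[axis] = n
    vol = np.asarray(values, dtype=float).reshape(shape)
    labels = np.ones(shape, dtype=np.int16)
    return roi_sample(vol, labels, 1, (1.0, 1.0, 1.0))


def ball_sample(radius, shape=None, spacing=(1.0, 1.0, 1.0), intensity=None, rng=None):
    if shape is None:
        n = int(2 * radius + 5)
        shape = (n, n, n)
    c = (np.array(shape) - 1) / 2
    g = np.indices(shape)
    mask = sum(((g[a] - c[a]) / radius) ** 2 for a in range(3)) <= 1.0
    if intensity is None:
        rng = rng or np.random.default_rng(0)
        intensity = 300 + 50 * rng.standard_normal(shape)
    return roi_sample(intensity, mask.astype(np.int16), 1, spacing)


@pytest.fixture(scope="session")
def small_cohort():
    cohort = generate_cohort(default_cohort_spec(seed=11))
    cohort, constants = normalize_scores(cohort)
    return cohort


@pytest.fixture(scope="session")
def small_phantom_spec():
    return default_phantom_spec(n_rois=4, shape=(20, 20, 20), radius=3.0)


@pytest.fixture(scope="session")
def null_feature_table(small_cohort, small_phantom_spec):
    """Feature table for a no-signal phantom cohort (77 subjects x 4 ROIs)."""
    rng = np.random.default_rng(np.random.SeedSequence((11, 101)))
    tables = [
        extract_all(
            *generate_phantom(row, small_phantom_spec, rng),
            subject_id=row["subject_id"],
        )
        for _, row in small_cohort.iterrows()
    ]
    return pd.concat(tables, ignore_index=True)
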