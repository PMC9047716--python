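"""Gray-level dependence matrix features (14 values).

A 26-neighbour of a voxel is *dependent* on it when their discretized
levels differ by at most the tolerance (0 here, i.e. equal levels).  The
matrix P(i, j) counts ROI voxels of level i whose dependence size is j,
where j = 1 + (number of dependent neighbours inside the ROI); counting
the centre voxel itself keeps j >= 1 so the 1/j^2 small-dependence
weights stay finite.  The centre of a constant 3x3x1 patch has 8
dependent neighbours, i.e. dependence size 9.
"""

from __future__ import annotations

import numpy as np

from ._glsm import size_matrix_stats
from .base import DIRECTIONS_3D, DiscretizedRoi, level_array, shifted_view

GLDM_FEATURE_NAMES = [
    "gldm_SmallDependenceEmphasis",
    "gldm_LargeDependenceEmphasis",
    "gldm_GrayLevelNonUniformity",
    "gldm_DependenceNonUniformity",
    "gldm_DependenceNonUniformityNormalized",
    "gldm_GrayLevelVariance",
    "gldm_DependenceVariance",
    "gldm_DependenceEntropy",
    "gldm_LowGrayLevelEmphasis",
    "gldm_HighGrayLevelEmphasis",
    "gldm_SmallDependenceLowGrayLevelEmphasis",
    "gldm_SmallDependenceHighGrayLevelEmphasis",
    "gldm_LargeDependenceLowGrayLevelEmphasis",
    "gldm_LargeDependenceHighGrayLevelEmphasis",
]


def dependence_counts(disc: DiscretizedRoi) -> np.ndarray:
    """Per-ROI-voxel count of dependent 26-neighbours (bounding-box array)."""
    arr = level_array(disc)
    core = arr[1:-1, 1:-1, 1:-1]
    dep = np.zeros(core.shape, dtype=np.int32)
    for d in DIRECTIONS_3D:
        dep += (core > 0) & (core == shifted_view(arr, d))
        dm = tuple(-c for c in d)
        dep += (core > 0) & (core == shifted_view(arr, dm))
    return dep


def gldm_matrix(disc: DiscretizedRoi) -> np.ndarray:
    arr = level_array(disc)[1:-1, 1:-1, 1:-1]
    dep = dependence_counts(disc)
    roi = arr > 0
    levels = arr[roi]
    sizes = dep[roi] + 1
    ng = disc.n_levels
    max_size = int(sizes.max())
    return np.bincount(
        (levels - 1) * max_size + (sizes - 1), minlength=ng * max_size
    ).reshape(ng, max_size).astype(np.float64)


def gldm_features(disc: DiscretizedRoi) -> dict[str, float]:
    s = size_matrix_stats(gldm_matrix(disc))
    return {
        "gldm_SmallDependenceEmphasis": s["small_emphasis"],
        "gldm_LargeDependenceEmphasis": s["large_emphasis"],
        "gldm_GrayLevelNonUniformity": s["gray_level_nonuniformity"],
        "gldm_DependenceNonUniformity": s["size_nonuniformity"],
        "gldm_DependenceNonUniformityNormalized": s["size_nonuniformity_normalized"],
        "gldm_GrayLevelVariance": s["gray_level_variance"],
        "gldm_DependenceVariance": s["size_variance"],
        "gldm_DependenceEntropy": s["entropy"],
        "gldm_LowGrayLevelEmphasis": s["low_gray_emphasis"],
        "gldm_HighGrayLevelEmphasis": s["high_gray_emphasis"],
        "gldm_SmallDependenceLowGrayLevelEmphasis": s["small_low"],
        "gldm_SmallDependenceHighGrayLevelEmphasis": s["small_high"],
        "gldm_LargeDependenceLowGrayLevelEmphasis": s["large_low"],
        "gldm_LargeDependenceHighGrayLevelEmphasis": s["large_high"],
    }
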