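"""Gray-level size-zone matrix features (16 values).

A zone is a 26-connected component of ROI voxels sharing one
discretized gray level; the (direction-free) matrix P(i, s) counts
zones of level i and size s.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._glsm import size_matrix_stats
from .base import DiscretizedRoi, level_array

GLSZM_FEATURE_NAMES = [
    "glszm_SmallAreaEmphasis",
    "glszm_LargeAreaEmphasis",
    "glszm_GrayLevelNonUniformity",
    "glszm_GrayLevelNonUniformityNormalized",
    "glszm_SizeZoneNonUniformity",
    "glszm_SizeZoneNonUniformityNormalized",
    "glszm_ZonePercentage",
    "glszm_GrayLevelVariance",
    "glszm_ZoneVariance",
    "glszm_ZoneEntropy",
    "glszm_LowGrayLevelZoneEmphasis",
    "glszm_HighGrayLevelZoneEmphasis",
    "glszm_SmallAreaLowGrayLevelEmphasis",
    "glszm_SmallAreaHighGrayLevelEmphasis",
    "glszm_LargeAreaLowGrayLevelEmphasis",
    "glszm_LargeAreaHighGrayLevelEmphasis",
]

_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(disc: DiscretizedRoi) -> np.ndarray:
    arr = level_array(disc)[1:-1, 1:-1, 1:-1]
    ng = disc.n_levels
    zones: list[tuple[int, int]] = []
    for g in np.unique(disc.bins):
        labeled, n = ndimage.label(arr == g, structure=_STRUCTURE)
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def glszm_features(disc: DiscretizedRoi) -> dict[str, float]:
    s = size_matrix_stats(glszm_matrix(disc))
    return {
        "glszm_SmallAreaEmphasis": s["small_emphasis"],
        "glszm_LargeAreaEmphasis": s["large_emphasis"],
        "glszm_GrayLevelNonUniformity": s["gray_level_nonuniformity"],
        "glszm_GrayLevelNonUniformityNormalized": s[
            "gray_level_nonuniformity_normalized"
        ],
        "glszm_SizeZoneNonUniformity": s["size_nonuniformity"],
        "glszm_SizeZoneNonUniformityNormalized": s["size_nonuniformity_normalized"],
        "glszm_ZonePercentage": s["n"] / disc.sample.n_voxels,
        "glszm_GrayLevelVariance": s["gray_level_variance"],
        "glszm_ZoneVariance": s["size_variance"],
        "glszm_ZoneEntropy": s["entropy"],
        "glszm_LowGrayLevelZoneEmphasis": s["low_gray_emphasis"],
        "glszm_HighGrayLevelZoneEmphasis": s["high_gray_emphasis"],
        "glszm_SmallAreaLowGrayLevelEmphasis": s["small_low"],
        "glszm_SmallAreaHighGrayLevelEmphasis": s["small_high"],
        "glszm_LargeAreaLowGrayLevelEmphasis": s["large_low"],
        "glszm_LargeAreaHighGrayLevelEmphasis": s["large_high"],
    }
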