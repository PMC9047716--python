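"""Gray-level run-length matrix features (16 values).

A run is a maximal sequence of consecutive ROI voxels with the same
discretized gray level along one of the 13 unique 3D directions.  One
run-length matrix P(i, j) (level i, length j) is built per direction;
features are evaluated per direction and averaged.  Every non-empty ROI
yields at least one run per direction, so no direction is ever skipped.

Runs are found by sorting the ROI voxels into the direction's parallel
lines: the cross product ``c x d`` of a voxel coordinate with the
direction is constant along a line, and the projection ``c . d``
advances by ``|d|^2`` per step, so after a lexsort on (line id,
projection) every run is a maximal stretch of sorted voxels with equal
level, equal line id, and unit step.
"""

from __future__ import annotations

import numpy as np

from ._glsm import size_matrix_stats
from .base import DIRECTIONS_3D, DiscretizedRoi

GLRLM_FEATURE_NAMES = [
    "glrlm_ShortRunEmphasis",
    "glrlm_LongRunEmphasis",
    "glrlm_GrayLevelNonUniformity",
    "glrlm_GrayLevelNonUniformityNormalized",
    "glrlm_RunLengthNonUniformity",
    "glrlm_RunLengthNonUniformityNormalized",
    "glrlm_RunPercentage",
    "glrlm_GrayLevelVariance",
    "glrlm_RunVariance",
    "glrlm_RunEntropy",
    "glrlm_LowGrayLevelRunEmphasis",
    "glrlm_HighGrayLevelRunEmphasis",
    "glrlm_ShortRunLowGrayLevelEmphasis",
    "glrlm_ShortRunHighGrayLevelEmphasis",
    "glrlm_LongRunLowGrayLevelEmphasis",
    "glrlm_LongRunHighGrayLevelEmphasis",
]


def _run_matrix(
    coords: np.ndarray, bins: np.ndarray, ng: int, d: tuple[int, int, int]
) -> np.ndarray:
    """Run-length count matrix for one direction."""
    t = coords @ np.asarray(d)
    line = (
        (coords[:, 0] * d[1] - coords[:, 1] * d[0]),
        (coords[:, 0] * d[2] - coords[:, 2] * d[0]),
        (coords[:, 1] * d[2] - coords[:, 2] * d[1]),
    )
    order = np.lexsort((t, *line))
    tb, bb = t[order], bins[order]
    step = int(np.dot(d, d))
    same_line = np.ones(len(order) - 1, dtype=bool)
    for key in line:
        same_line &= key[order][1:] == key[order][:-1]
    joined = same_line & (tb[1:] - tb[:-1] == step) & (bb[1:] == bb[:-1])
    starts = np.flatnonzero(np.concatenate(([True], ~joined)))
    lengths = np.diff(np.append(starts, len(order)))
    levels = bb[starts]
    max_len = int(lengths.max())
    return np.bincount(
        (levels - 1) * max_len + (lengths - 1), minlength=ng * max_len
    ).reshape(ng, max_len)


def glrlm_matrices(disc: DiscretizedRoi) -> list[np.ndarray]:
    coords = disc.sample.coords
    return [
        _run_matrix(coords, disc.bins, disc.n_levels, d) for d in DIRECTIONS_3D
    ]


def glrlm_features(disc: DiscretizedRoi) -> dict[str, float]:
    n_vox = disc.sample.n_voxels
    mats = glrlm_matrices(disc)
    jmax = max(m.shape[1] for m in mats)
    stack = np.stack(
        [np.pad(m, ((0, 0), (0, jmax - m.shape[1]))) for m in mats]
    )
    s = size_matrix_stats(stack)  # arrays over the 13 directions
    renamed = {
        "glrlm_ShortRunEmphasis": s["small_emphasis"],
        "glrlm_LongRunEmphasis": s["large_emphasis"],
        "glrlm_GrayLevelNonUniformity": s["gray_level_nonuniformity"],
        "glrlm_GrayLevelNonUniformityNormalized": s[
            "gray_level_nonuniformity_normalized"
        ],
        "glrlm_RunLengthNonUniformity": s["size_nonuniformity"],
        "glrlm_RunLengthNonUniformityNormalized": s["size_nonuniformity_normalized"],
        "glrlm_RunPercentage": s["n"] / n_vox,
        "glrlm_GrayLevelVariance": s["gray_level_variance"],
        "glrlm_RunVariance": s["size_variance"],
        "glrlm_RunEntropy": s["entropy"],
        "glrlm_LowGrayLevelRunEmphasis": s["low_gray_emphasis"],
        "glrlm_HighGrayLevelRunEmphasis": s["high_gray_emphasis"],
        "glrlm_ShortRunLowGrayLevelEmphasis": s["small_low"],
        "glrlm_ShortRunHighGrayLevelEmphasis": s["small_high"],
        "glrlm_LongRunLowGrayLevelEmphasis": s["large_low"],
        "glrlm_LongRunHighGrayLevelEmphasis": s["large_high"],
    }
    return {name: float(renamed[name].mean()) for name in GLRLM_FEATURE_NAMES}
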