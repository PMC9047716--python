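"""Gray-level co-occurrence matrix features (22 values).

One symmetric GLCM per unique 3D unit-offset direction (13 in total) at
distance 1; each matrix is normalized to sum to 1, the features are
evaluated per direction and averaged.  Directions with no valid voxel
pair are excluded from the average; if *no* direction yields a pair
(single-voxel ROI) the matrix degenerates to a single cell of
probability 1 at the voxel's own level.

Logs are base 2 with 0*log(0) := 0.  Degenerate conventions: for a flat
matrix (zero marginal variance) Correlation := 1 and Imc1 := 0; both are
the analytic limits of perfectly dependent marginals.

The per-direction matrices are stacked and all features evaluated in
one broadcast pass; per-level index maps are cached per matrix size.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .base import DIRECTIONS_3D, DiscretizedRoi, level_array, shifted_view

GLCM_FEATURE_NAMES = [
    "glcm_Autocorrelation",
    "glcm_ClusterProminence",
    "glcm_ClusterShade",
    "glcm_ClusterTendency",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_DifferenceAverage",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_Id",
    "glcm_Idm",
    "glcm_Idmn",
    "glcm_Idn",
    "glcm_Imc1",
    "glcm_Imc2",
    "glcm_InverseVariance",
    "glcm_JointAverage",
    "glcm_JointEnergy",
    "glcm_JointEntropy",
    "glcm_MaximumProbability",
    "glcm_SumEntropy",
    "glcm_SumSquares",
]


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


@lru_cache(maxsize=64)
def _index_maps(ng: int):
    """Level grids and scatter maps from (i, j) cells to |i-j| and i+j bands."""
    levels = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    diff_idx = np.abs(ii - jj).astype(np.intp).ravel()
    sum_idx = (ii + jj - 2).astype(np.intp).ravel()
    M_diff = np.zeros((ng * ng, ng))
    M_diff[np.arange(ng * ng), diff_idx] = 1.0
    M_sum = np.zeros((ng * ng, 2 * ng - 1))
    M_sum[np.arange(ng * ng), sum_idx] = 1.0
    return levels, ii, jj, M_diff, M_sum


def glcm_matrices(disc: DiscretizedRoi) -> list[np.ndarray]:
    """Normalized symmetric co-occurrence matrices, one per valid direction."""
    arr = level_array(disc)
    core = arr[1:-1, 1:-1, 1:-1]
    ng = disc.n_levels
    matrices = []
    for d in DIRECTIONS_3D:
        nb = shifted_view(arr, d)
        valid = (core > 0) & (nb > 0)
        if not valid.any():
            continue
        i = core[valid].ravel()
        j = nb[valid].ravel()
        counts = np.bincount(
            (i - 1) * ng + (j - 1), minlength=ng * ng
        ).reshape(ng, ng)
        sym = counts + counts.T
        matrices.append(sym / sym.sum())
    if not matrices:
        # single-voxel ROI: one self co-occurrence at its own level
        m = np.zeros((ng, ng))
        m[disc.bins[0] - 1, disc.bins[0] - 1] = 1.0
        matrices.append(m)
    return matrices


def _features_batch(P: np.ndarray) -> dict[str, np.ndarray]:
    """All 22 features for a stack of normalized matrices, shape (D, ng, ng)."""
    D, ng, _ = P.shape
    levels, ii, jj, M_diff, M_sum = _index_maps(ng)

    px = P.sum(axis=2)  # (D, ng); symmetric: px == py
    mu = px @ levels
    dev = levels[None, :] - mu[:, None]
    sigma2 = (dev**2 * px).sum(axis=1)

    p_flat = P.reshape(D, -1)
    p_diff = p_flat @ M_diff  # (D, ng), band k = |i-j|
    p_sum = p_flat @ M_sum  # (D, 2ng-1), band k = i+j
    k_diff = np.arange(ng, dtype=np.float64)
    diff_avg = p_diff @ k_diff

    hxy = -_xlog2x(p_flat).sum(axis=1)
    outer = (px[:, :, None] * px[:, None, :]).reshape(D, -1)
    log_outer = np.zeros_like(outer)
    nz = outer > 0
    log_outer[nz] = np.log2(outer[nz])
    hxy1 = -(p_flat * log_outer).sum(axis=1)  # p>0 implies both marginals >0
    hxy2 = -_xlog2x(outer).sum(axis=1)
    hx = -_xlog2x(px).sum(axis=1)

    safe_hx = np.where(hx > 0, hx, 1.0)
    imc1 = np.where(hx > 0, (hxy - hxy1) / safe_hx, 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    autocorr = ((ii * jj)[None] * P).sum(axis=(1, 2))
    safe_s2 = np.where(sigma2 > 0, sigma2, 1.0)
    correlation = np.where(sigma2 > 0, (autocorr - mu**2) / safe_s2, 1.0)

    cluster = (ii + jj)[None] - 2.0 * mu[:, None, None]
    inv_var = (
        (p_diff[:, 1:] / k_diff[1:] ** 2).sum(axis=1) if ng > 1 else np.zeros(D)
    )

    return {
        "glcm_Autocorrelation": autocorr,
        "glcm_ClusterProminence": (cluster**4 * P).sum(axis=(1, 2)),
        "glcm_ClusterShade": (cluster**3 * P).sum(axis=(1, 2)),
        "glcm_ClusterTendency": (cluster**2 * P).sum(axis=(1, 2)),
        "glcm_Contrast": (((ii - jj) ** 2)[None] * P).sum(axis=(1, 2)),
        "glcm_Correlation": correlation,
        "glcm_DifferenceAverage": diff_avg,
        "glcm_DifferenceEntropy": -_xlog2x(p_diff).sum(axis=1),
        "glcm_DifferenceVariance": (
            (k_diff[None, :] - diff_avg[:, None]) ** 2 * p_diff
        ).sum(axis=1),
        "glcm_Id": (p_diff / (1.0 + k_diff)).sum(axis=1),
        "glcm_Idm": (p_diff / (1.0 + k_diff**2)).sum(axis=1),
        "glcm_Idmn": (p_diff / (1.0 + (k_diff / ng) ** 2)).sum(axis=1),
        "glcm_Idn": (p_diff / (1.0 + k_diff / ng)).sum(axis=1),
        "glcm_Imc1": imc1,
        "glcm_Imc2": imc2,
        "glcm_InverseVariance": inv_var,
        "glcm_JointAverage": mu,
        "glcm_JointEnergy": (p_flat**2).sum(axis=1),
        "glcm_JointEntropy": hxy,
        "glcm_MaximumProbability": p_flat.max(axis=1),
        "glcm_SumEntropy": -_xlog2x(p_sum).sum(axis=1),
        "glcm_SumSquares": sigma2,
    }


def glcm_features(disc: DiscretizedRoi) -> dict[str, float]:
    stack = np.stack(glcm_matrices(disc))
    feats = _features_batch(stack)
    return {name: float(feats[name].mean()) for name in GLCM_FEATURE_NAMES}
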