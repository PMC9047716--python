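"""Shared statistics for gray-level/size-type matrices.

GLRLM, GLSZM and GLDM all reduce to a count matrix P(i, j) with rows
indexed by gray level i = 1..Ng and columns by a size attribute
j = 1..Jmax (run length, zone size, or dependence size).  The classic
feature sets of the three families are the same weighted sums with
different names; this module computes them once, batched over a stack
of matrices (e.g. the 13 run-length directions at once).
"""

from __future__ import annotations

import numpy as np


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def size_matrix_stats(P: np.ndarray) -> dict[str, np.ndarray]:
    """Standard emphasis / non-uniformity / variance stats of P(i, j).

    ``P`` is (ng, jmax) or a stack (D, ng, jmax); every returned value
    is scalar-like with the stack's leading shape.  Keys are generic;
    family modules rename them.  ``n`` is the total count (runs /
    zones / voxels).
    """
    P = np.asarray(P, dtype=np.float64)
    squeeze = P.ndim == 2
    if squeeze:
        P = P[None]
    D, ng, jmax = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[None, :, None]
    j = np.arange(1, jmax + 1, dtype=np.float64)[None, None, :]

    n = P.sum(axis=(1, 2))
    p = P / n[:, None, None]
    pg = P.sum(axis=2)  # (D, ng)
    ps = P.sum(axis=1)  # (D, jmax)

    mu_i = (p * i).sum(axis=(1, 2))
    mu_j = (p * j).sum(axis=(1, 2))

    out = {
        "n": n,
        "small_emphasis": (P / j**2).sum(axis=(1, 2)) / n,
        "large_emphasis": (P * j**2).sum(axis=(1, 2)) / n,
        "gray_level_nonuniformity": (pg**2).sum(axis=1) / n,
        "gray_level_nonuniformity_normalized": (pg**2).sum(axis=1) / n**2,
        "size_nonuniformity": (ps**2).sum(axis=1) / n,
        "size_nonuniformity_normalized": (ps**2).sum(axis=1) / n**2,
        "gray_level_variance": (p * (i - mu_i[:, None, None]) ** 2).sum(axis=(1, 2)),
        "size_variance": (p * (j - mu_j[:, None, None]) ** 2).sum(axis=(1, 2)),
        "entropy": -_xlog2x(p).sum(axis=(1, 2)),
        "low_gray_emphasis": (P / i**2).sum(axis=(1, 2)) / n,
        "high_gray_emphasis": (P * i**2).sum(axis=(1, 2)) / n,
        "small_low": (P / (i**2 * j**2)).sum(axis=(1, 2)) / n,
        "small_high": (P * i**2 / j**2).sum(axis=(1, 2)) / n,
        "large_low": (P * j**2 / i**2).sum(axis=(1, 2)) / n,
        "large_high": (P * i**2 * j**2).sum(axis=(1, 2)) / n,
    }
    if squeeze:
        out = {k: float(v[0]) for k, v in out.items()}
    return out
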