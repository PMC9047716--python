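"""Brute-force reference implementations of the 100-feature catalog.

Every feature is recomputed here from its textbook formula with plain
Python loops over voxels, matrix cells, runs, and zones — no sharing of
the vectorized production code paths.  The only shared primitives are
the marching-cubes mesh extraction (scikit-image) and the symmetric
eigendecomposition, both library calls; area, volume, and all sums over
mesh triangles or matrix entries are accumulated by explicit iteration.

Intended for small ROIs (<= a few hundred voxels); complexity is
whatever the naive formula costs.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.measure import marching_cubes

DIRS_13 = [
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) > (0, 0, 0)
]
DIRS_26 = [
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) != (0, 0, 0)
]


def log2_safe(p):
    return math.log2(p) if p > 0 else 0.0


def ref_discretize(values, width):
    vmin = min(values)
    return [int(math.floor((v - vmin) / width)) + 1 for v in values]


def ref_percentile(values, q):
    """Linear interpolation between order statistics."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    rank = q / 100.0 * (n - 1)
    lo = int(math.floor(rank))
    hi = min(lo + 1, n - 1)
    frac = rank - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def ref_firstorder(values, bins, voxel_volume):
    n = len(values)
    mean = sum(values) / n
    energy = sum(v * v for v in values)
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    p10 = ref_percentile(values, 10)
    p90 = ref_percentile(values, 90)
    robust = [v for v in values if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    counts: dict[int, int] = {}
    for b in bins:
        counts[b] = counts.get(b, 0) + 1
    probs = [c / n for c in counts.values()]
    return {
        "firstorder_Energy": energy,
        "firstorder_TotalEnergy": energy * voxel_volume,
        "firstorder_Entropy": -sum(p * log2_safe(p) for p in probs),
        "firstorder_Minimum": min(values),
        "firstorder_10Percentile": p10,
        "firstorder_90Percentile": p90,
        "firstorder_Maximum": max(values),
        "firstorder_Mean": mean,
        "firstorder_Median": ref_percentile(values, 50),
        "firstorder_InterquartileRange": ref_percentile(values, 75) - ref_percentile(values, 25),
        "firstorder_Range": max(values) - min(values),
        "firstorder_MeanAbsoluteDeviation": sum(abs(v - mean) for v in values) / n,
        "firstorder_RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "firstorder_RootMeanSquared": math.sqrt(energy / n),
        "firstorder_Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "firstorder_Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "firstorder_Variance": m2,
        "firstorder_Uniformity": sum(p * p for p in probs),
    }


def ref_shape(coords, spacing):
    coords = [tuple(int(c) for c in p) for p in coords]
    spacing = tuple(float(s) for s in spacing)
    n = len(coords)
    lo = [min(p[a] for p in coords) for a in range(3)]
    hi = [max(p[a] for p in coords) for a in range(3)]
    mask = np.zeros([hi[a] - lo[a] + 3 for a in range(3)])
    for p in coords:
        mask[p[0] - lo[0] + 1, p[1] - lo[1] + 1, p[2] - lo[2] + 1] = 1.0
    verts, faces, _, _ = marching_cubes(mask, level=0.5, spacing=spacing)

    area = 0.0
    vol6 = 0.0
    for f in faces:
        a, b, c = (verts[f[0]], verts[f[1]], verts[f[2]])
        ab = [b[i] - a[i] for i in range(3)]
        ac = [c[i] - a[i] for i in range(3)]
        cr = [
            ab[1] * ac[2] - ab[2] * ac[1],
            ab[2] * ac[0] - ab[0] * ac[2],
            ab[0] * ac[1] - ab[1] * ac[0],
        ]
        area += 0.5 * math.sqrt(sum(x * x for x in cr))
        bc_cr = [
            b[1] * c[2] - b[2] * c[1],
            b[2] * c[0] - b[0] * c[2],
            b[0] * c[1] - b[1] * c[0],
        ]
        vol6 += sum(a[i] * bc_cr[i] for i in range(3))
    volume = abs(vol6) / 6.0

    pts = [[p[a] * spacing[a] for a in range(3)] for p in coords]

    def max_pair(points):
        best = 0.0
        for i in range(len(points)):
            for j in range(i + 1, len(points)):
                d = math.dist(points[i], points[j])
                best = max(best, d)
        return best

    diam3d = max_pair(pts)
    diam2d = {}
    for name, axis in [("Slice", 0), ("Column", 1), ("Row", 2)]:
        best = 0.0
        for value in {p[axis] for p in coords}:
            group = [
                [pt[a] for a in range(3) if a != axis]
                for p, pt in zip(coords, pts)
                if p[axis] == value
            ]
            best = max(best, max_pair(group))
        diam2d[name] = best

    centroid = [sum(p[a] for p in pts) / n for a in range(3)]
    cov = np.zeros((3, 3))
    for p in pts:
        for a in range(3):
            for b in range(3):
                cov[a, b] += (p[a] - centroid[a]) * (p[b] - centroid[b])
    cov /= n
    for a in range(3):
        cov[a, a] += spacing[a] ** 2 / 12.0
    least, minor, major = [max(v, 0.0) for v in np.linalg.eigvalsh(cov)]

    vox_vol = spacing[0] * spacing[1] * spacing[2]
    return {
        "shape_MeshVolume": volume,
        "shape_VoxelVolume": n * vox_vol,
        "shape_SurfaceArea": area,
        "shape_SurfaceVolumeRatio": area / volume,
        "shape_Sphericity": (36.0 * math.pi * volume**2) ** (1.0 / 3.0) / area,
        "shape_Maximum3DDiameter": diam3d,
        "shape_Maximum2DDiameterSlice": diam2d["Slice"],
        "shape_Maximum2DDiameterColumn": diam2d["Column"],
        "shape_Maximum2DDiameterRow": diam2d["Row"],
        "shape_MajorAxisLength": 4.0 * math.sqrt(major),
        "shape_MinorAxisLength": 4.0 * math.sqrt(minor),
        "shape_LeastAxisLength": 4.0 * math.sqrt(least),
        "shape_Elongation": math.sqrt(minor / major),
        "shape_Flatness": math.sqrt(least / major),
    }


def _glcm_features_from(p, ng):
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i][j]
            p_sum[i + j] += p[i][j]
    diff_avg = sum(k * p_diff[k] for k in range(ng))
    hxy = -sum(p[i][j] * log2_safe(p[i][j]) for i in range(ng) for j in range(ng))
    hxy1 = -sum(
        p[i][j] * log2_safe(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * log2_safe(px[i] * px[j]) for i in range(ng) for j in range(ng)
    )
    hx = -sum(q * log2_safe(q) for q in px)
    autocorr = sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
    return {
        "glcm_Autocorrelation": autocorr,
        "glcm_ClusterProminence": sum(
            (i + j + 2 - 2 * mu) ** 4 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "glcm_ClusterShade": sum(
            (i + j + 2 - 2 * mu) ** 3 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "glcm_ClusterTendency": sum(
            (i + j + 2 - 2 * mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "glcm_Contrast": sum(
            (i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "glcm_Correlation": (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 1.0,
        "glcm_DifferenceAverage": diff_avg,
        "glcm_DifferenceEntropy": -sum(q * log2_safe(q) for q in p_diff),
        "glcm_DifferenceVariance": sum(
            (k - diff_avg) ** 2 * p_diff[k] for k in range(ng)
        ),
        "glcm_Id": sum(p_diff[k] / (1.0 + k) for k in range(ng)),
        "glcm_Idm": sum(p_diff[k] / (1.0 + k * k) for k in range(ng)),
        "glcm_Idmn": sum(p_diff[k] / (1.0 + (k / ng) ** 2) for k in range(ng)),
        "glcm_Idn": sum(p_diff[k] / (1.0 + k / ng) for k in range(ng)),
        "glcm_Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "glcm_Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "glcm_InverseVariance": sum(p_diff[k] / k**2 for k in range(1, ng)),
        "glcm_JointAverage": mu,
        "glcm_JointEnergy": sum(
            p[i][j] ** 2 for i in range(ng) for j in range(ng)
        ),
        "glcm_JointEntropy": hxy,
        "glcm_MaximumProbability": max(max(row) for row in p),
        "glcm_SumEntropy": -sum(q * log2_safe(q) for q in p_sum),
        "glcm_SumSquares": sigma2,
    }


def ref_glcm(coords, bins):
    ng = max(bins)
    level = {tuple(p): b for p, b in zip(map(tuple, coords), bins)}
    per_dir = []
    for d in DIRS_13:
        counts = [[0.0] * ng for _ in range(ng)]
        total = 0
        for p, i in level.items():
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if q in level:
                j = level[q]
                counts[i - 1][j - 1] += 1
                counts[j - 1][i - 1] += 1
                total += 2
        if total:
            per_dir.append(
                _glcm_features_from(
                    [[c / total for c in row] for row in counts], ng
                )
            )
    if not per_dir:
        counts = [[0.0] * ng for _ in range(ng)]
        counts[bins[0] - 1][bins[0] - 1] = 1.0
        per_dir.append(_glcm_features_from(counts, ng))
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in per_dir[0]}


def _size_stats(entries, n_vox):
    """entries: list of (gray level i, size j, count)."""
    n = sum(c for _, _, c in entries)
    mu_i = sum(i * c for i, _, c in entries) / n
    mu_j = sum(j * c for _, j, c in entries) / n
    pg: dict[int, float] = {}
    ps: dict[int, float] = {}
    for i, j, c in entries:
        pg[i] = pg.get(i, 0.0) + c
        ps[j] = ps.get(j, 0.0) + c
    return {
        "n": n,
        "small_emphasis": sum(c / j**2 for _, j, c in entries) / n,
        "large_emphasis": sum(c * j**2 for _, j, c in entries) / n,
        "gray_level_nonuniformity": sum(v**2 for v in pg.values()) / n,
        "gray_level_nonuniformity_normalized": sum(v**2 for v in pg.values()) / n**2,
        "size_nonuniformity": sum(v**2 for v in ps.values()) / n,
        "size_nonuniformity_normalized": sum(v**2 for v in ps.values()) / n**2,
        "percentage": n / n_vox,
        "gray_level_variance": sum((i - mu_i) ** 2 * c for i, _, c in entries) / n,
        "size_variance": sum((j - mu_j) ** 2 * c for _, j, c in entries) / n,
        "entropy": -sum((c / n) * log2_safe(c / n) for _, _, c in entries),
        "low_gray_emphasis": sum(c / i**2 for i, _, c in entries) / n,
        "high_gray_emphasis": sum(c * i**2 for i, _, c in entries) / n,
        "small_low": sum(c / (i**2 * j**2) for i, j, c in entries) / n,
        "small_high": sum(c * i**2 / j**2 for i, j, c in entries) / n,
        "large_low": sum(c * j**2 / i**2 for i, j, c in entries) / n,
        "large_high": sum(c * i**2 * j**2 for i, j, c in entries) / n,
    }


def _collect(pairs):
    out: dict[tuple[int, int], int] = {}
    for key in pairs:
        out[key] = out.get(key, 0) + 1
    return [(i, j, c) for (i, j), c in out.items()]


def ref_glrlm(coords, bins):
    level = {tuple(p): b for p, b in zip(map(tuple, coords), bins)}
    n_vox = len(bins)
    per_dir = []
    for d in DIRS_13:
        runs = []
        for p, g in level.items():
            prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
            if level.get(prev) == g:
                continue  # not a run start
            length = 1
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            while level.get(q) == g:
                length += 1
                q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
            runs.append((g, length))
        s = _size_stats(_collect(runs), n_vox)
        per_dir.append(
            {
                "glrlm_ShortRunEmphasis": s["small_emphasis"],
                "glrlm_LongRunEmphasis": s["large_emphasis"],
                "glrlm_GrayLevelNonUniformity": s["gray_level_nonuniformity"],
                "glrlm_GrayLevelNonUniformityNormalized": s["gray_level_nonuniformity_normalized"],
                "glrlm_RunLengthNonUniformity": s["size_nonuniformity"],
                "glrlm_RunLengthNonUniformityNormalized": s["size_nonuniformity_normalized"],
                "glrlm_RunPercentage": s["percentage"],
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
        )
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in per_dir[0]}


def ref_glszm(coords, bins):
    level = {tuple(p): b for p, b in zip(map(tuple, coords), bins)}
    n_vox = len(bins)
    seen = set()
    zones = []
    for start in level:
        if start in seen:
            continue
        g = level[start]
        stack = [start]
        seen.add(start)
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in DIRS_26:
                q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if q not in seen and level.get(q) == g:
                    seen.add(q)
                    stack.append(q)
        zones.append((g, size))
    s = _size_stats(_collect(zones), n_vox)
    return {
        "glszm_SmallAreaEmphasis": s["small_emphasis"],
        "glszm_LargeAreaEmphasis": s["large_emphasis"],
        "glszm_GrayLevelNonUniformity": s["gray_level_nonuniformity"],
        "glszm_GrayLevelNonUniformityNormalized": s["gray_level_nonuniformity_normalized"],
        "glszm_SizeZoneNonUniformity": s["size_nonuniformity"],
        "glszm_SizeZoneNonUniformityNormalized": s["size_nonuniformity_normalized"],
        "glszm_ZonePercentage": s["percentage"],
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


def ref_gldm(coords, bins):
    level = {tuple(p): b for p, b in zip(map(tuple, coords), bins)}
    entries = []
    for p, g in level.items():
        dep = 0
        for d in DIRS_26:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if level.get(q) == g:
                dep += 1
        entries.append((g, dep + 1))
    s = _size_stats(_collect(entries), len(bins))
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


def ref_extract_roi(coords, values, spacing, bin_width=25.0):
    """All 100 catalog features by brute force."""
    values = [float(v) for v in values]
    bins = ref_discretize(values, bin_width)
    vox_vol = float(spacing[0] * spacing[1] * spacing[2])
    out = {}
    out.update(ref_shape(coords, spacing))
    out.update(ref_firstorder(values, bins, vox_vol))
    out.update(ref_glcm(coords, bins))
    out.update(ref_glrlm(coords, bins))
    out.update(ref_glszm(coords, bins))
    out.update(ref_gldm(coords, bins))
    return out
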