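"""First-order (intensity histogram) features, 18 values.

All statistics are computed on the raw ROI intensities except Entropy
and Uniformity, which operate on the fixed-bin-width discretized
histogram.  Percentiles use linear interpolation between order
statistics; moments are population moments (ddof = 0).  Zero-variance
ROIs take Skewness = Kurtosis = 0 by convention so feature vectors stay
finite; Kurtosis is not Fisher-corrected (a normal sample gives ~3).
"""

from __future__ import annotations

import numpy as np

from .base import DiscretizedRoi, RoiSample


def first_order_features(sample: RoiSample, disc: DiscretizedRoi) -> dict[str, float]:
    x = sample.intensities
    n = x.size
    energy = float(np.sum(x**2))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mean = float(np.mean(x))
    m2 = float(np.mean((x - mean) ** 2))
    if m2 > 0:
        skewness = float(np.mean((x - mean) ** 3) / m2**1.5)
        kurtosis = float(np.mean((x - mean) ** 4) / m2**2)
    else:
        skewness = kurtosis = 0.0

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0

    counts = np.bincount(disc.bins)[1:]
    p = counts[counts > 0] / n
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p**2))

    return {
        "firstorder_Energy": energy,
        "firstorder_TotalEnergy": energy * sample.voxel_volume,
        "firstorder_Entropy": entropy,
        "firstorder_Minimum": float(x.min()),
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_Maximum": float(x.max()),
        "firstorder_Mean": mean,
        "firstorder_Median": float(p50),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_Range": float(x.max() - x.min()),
        "firstorder_MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "firstorder_RobustMeanAbsoluteDeviation": rmad,
        "firstorder_RootMeanSquared": float(np.sqrt(energy / n)),
        "firstorder_Skewness": skewness,
        "firstorder_Kurtosis": kurtosis,
        "firstorder_Variance": m2,
        "firstorder_Uniformity": uniformity,
    }
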