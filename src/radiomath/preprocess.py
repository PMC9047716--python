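"""Whole-volume intensity standardization by histogram matching.

Each subject's volume is mapped so its empirical intensity CDF matches
that of a reference subject; this is the standardization step applied
before any per-ROI feature extraction.  Bias-field correction and
spatial registration are out of scope: the pipeline consumes label maps
already in native space.
"""

from __future__ import annotations

import numpy as np
from skimage.exposure import match_histograms


def histogram_match(volume: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map ``volume`` so its intensity histogram matches ``reference``.

    Raises for empty inputs or a constant reference (the quantile
    mapping is undefined when the reference has a single value).
    """
    volume = np.asarray(volume, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if volume.size == 0 or reference.size == 0:
        raise ValueError("volumes must be non-empty")
    if np.ptp(reference) == 0:
        raise ValueError("constant reference volume: histogram matching undefined")
    return match_histograms(volume, reference)
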