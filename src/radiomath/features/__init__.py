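"""Per-ROI radiomics feature extraction (the fixed 100-feature catalog).

`extract_roi` computes the full catalog for a single ROI; `extract_all`
walks every label of a label volume and returns a tidy table with one
row per (subject, ROI) and one column per catalog feature.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..catalog import CATALOG
from .base import (
    DEFAULT_BIN_WIDTH,
    DIRECTIONS_3D,
    DiscretizedRoi,
    RoiSample,
    discretize,
    level_array,
)
from .firstorder import first_order_features
from .gldm import gldm_features, gldm_matrix
from .glcm import glcm_features, glcm_matrices
from .glrlm import glrlm_features, glrlm_matrices
from .glszm import glszm_features, glszm_matrix
from .shape import shape_features

__all__ = [
    "DEFAULT_BIN_WIDTH",
    "DIRECTIONS_3D",
    "DiscretizedRoi",
    "RoiSample",
    "discretize",
    "extract_all",
    "extract_roi",
    "first_order_features",
    "gldm_features",
    "gldm_matrix",
    "glcm_features",
    "glcm_matrices",
    "glrlm_features",
    "glrlm_matrices",
    "glszm_features",
    "glszm_matrix",
    "level_array",
    "shape_features",
]

logger = logging.getLogger(__name__)


def roi_sample(
    intensity: np.ndarray,
    labels: np.ndarray,
    label: int,
    spacing=(1.0, 1.0, 1.0),
    subject_id: str = "",
) -> RoiSample:
    """Pull one ROI's voxels out of an intensity/label volume pair."""
    if intensity.shape != labels.shape:
        raise ValueError("intensity and label volumes differ in shape")
    coords = np.argwhere(labels == label)
    if coords.size == 0:
        raise ValueError(f"label {label} absent from label volume")
    values = intensity[coords[:, 0], coords[:, 1], coords[:, 2]]
    return RoiSample(
        intensities=values,
        coords=coords,
        spacing=np.asarray(spacing, dtype=float),
        roi_label=int(label),
        subject_id=subject_id,
    )


def extract_roi(sample: RoiSample, bin_width: float = DEFAULT_BIN_WIDTH) -> dict[str, float]:
    """All 100 catalog features for one ROI, in canonical order."""
    disc = discretize(sample, bin_width)
    values: dict[str, float] = {}
    values.update(shape_features(sample))
    values.update(first_order_features(sample, disc))
    values.update(glcm_features(disc))
    values.update(glrlm_features(disc))
    values.update(glszm_features(disc))
    values.update(gldm_features(disc))
    return {name: values[name] for name in CATALOG}


def extract_all(
    intensity: np.ndarray,
    labels: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    bin_width: float = DEFAULT_BIN_WIDTH,
    subject_id: str = "",
    expected_labels=None,
) -> pd.DataFrame:
    """Feature table for every ROI of one subject.

    ``expected_labels`` may list labels that must appear; a configured
    label missing from the volume is reported with a row of NaN rather
    than silently dropped.
    """
    present = [int(v) for v in np.unique(labels) if v != 0]
    wanted = present if expected_labels is None else [int(v) for v in expected_labels]
    rows = []
    for label in wanted:
        row: dict[str, object] = {"subject_id": subject_id, "roi_label": label}
        if label in present:
            sample = roi_sample(intensity, labels, label, spacing, subject_id)
            row.update(extract_roi(sample, bin_width))
        else:
            logger.warning("label %d expected but absent; emitting NaN row", label)
            row.update({name: np.nan for name in CATALOG})
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "roi_label", *CATALOG])
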