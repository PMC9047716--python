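"""Canonical 100-feature radiomics catalog and the behavioural test battery.

The catalog fixes the identity, order, and family assignment of every
feature the pipeline computes per (subject, ROI).  Order matters twice:
feature tables are emitted in this order, and the sequential
correlation-based feature selection walks the catalog front to back, so
shape features (listed first) win ties against correlated texture
features.

Families follow the reporting convention of the analysis: ``volume``
(mesh and voxel volume) is split out of ``shape`` so its contribution to
model importance can be assessed separately; all first-order features
are ``intensity``; the four texture-matrix families are pooled as
``texture``.  ``age``, the covariate entered alongside the image
features, forms its own family.
"""

from __future__ import annotations

SHAPE_FEATURES = [
    "shape_MeshVolume",
    "shape_VoxelVolume",
    "shape_SurfaceArea",
    "shape_SurfaceVolumeRatio",
    "shape_Sphericity",
    "shape_Maximum3DDiameter",
    "shape_Maximum2DDiameterSlice",
    "shape_Maximum2DDiameterColumn",
    "shape_Maximum2DDiameterRow",
    "shape_MajorAxisLength",
    "shape_MinorAxisLength",
    "shape_LeastAxisLength",
    "shape_Elongation",
    "shape_Flatness",
]

FIRSTORDER_FEATURES = [
    "firstorder_Energy",
    "firstorder_TotalEnergy",
    "firstorder_Entropy",
    "firstorder_Minimum",
    "firstorder_10Percentile",
    "firstorder_90Percentile",
    "firstorder_Maximum",
    "firstorder_Mean",
    "firstorder_Median",
    "firstorder_InterquartileRange",
    "firstorder_Range",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_Skewness",
    "firstorder_Kurtosis",
    "firstorder_Variance",
    "firstorder_Uniformity",
]

GLCM_FEATURES = [
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

GLRLM_FEATURES = [
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

GLSZM_FEATURES = [
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

GLDM_FEATURES = [
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

#: Canonical extraction/selection order: shape first, then first-order,
#: then the texture families.
CATALOG = (
    SHAPE_FEATURES
    + FIRSTORDER_FEATURES
    + GLCM_FEATURES
    + GLRLM_FEATURES
    + GLSZM_FEATURES
    + GLDM_FEATURES
)

VOLUME_FEATURES = ["shape_MeshVolume", "shape_VoxelVolume"]

#: feature name -> reporting family
FAMILY_OF = {}
for _name in SHAPE_FEATURES:
    FAMILY_OF[_name] = "volume" if _name in VOLUME_FEATURES else "shape"
for _name in FIRSTORDER_FEATURES:
    FAMILY_OF[_name] = "intensity"
for _name in GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES + GLDM_FEATURES:
    FAMILY_OF[_name] = "texture"
FAMILY_OF["age"] = "age"

FAMILIES = ["age", "volume", "shape", "intensity", "texture"]

assert len(CATALOG) == 100
assert len(set(CATALOG)) == 100

#: WJ-III achievement battery: short key -> (full test name, maximum raw score)
TESTS = {
    "mf": ("Math fluency", 160),
    "calc": ("Calculation", 46),
    "ap": ("Applied problems", 62),
    "qc": ("Quantitative concepts", 57),
}

TEST_KEYS = list(TESTS)

#: cohort-table column per test (raw integer scores)
SCORE_COLUMNS = {key: f"{key}_raw" for key in TESTS}
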