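"""Gini-importance aggregation by feature family.

Random forests report, per fitted model, a mean-decrease-of-impurity
(Gini) importance per input feature, normalized to sum to 1.  For an
area, importances are averaged over *all* models of all partitions
(features removed by selection in a partition contribute 0 there, which
keeps family shares comparable across partitions with different kept
sets), summed by family — age, volume, shape, intensity, texture, with
volume split out of shape so its contribution is visible on its own —
and rescaled to percentages.

As a proxy for feature stability, the across-model standard deviation
of each feature's importance is computed and features whose variability
exceeds the mean variability by more than two (population) standard
deviations are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import FAMILIES, FAMILY_OF


@dataclass
class ImportanceBreakdown:
    family_percent: dict[str, float]
    mean_importance: dict[str, float]
    sd_importance: dict[str, float]
    flagged_features: list[str]


def flag_unstable(sds, names=None) -> list:
    """Indices (or names) of features with SD > mean + 2 * population SD."""
    sds = np.asarray(sds, dtype=float).ravel()
    if sds.size < 3:
        raise ValueError("need at least 3 features to flag outliers")
    threshold = sds.mean() + 2.0 * sds.std(ddof=0)
    idx = np.flatnonzero(sds > threshold)
    if names is None:
        return idx.tolist()
    return [names[i] for i in idx]


def family_importance(
    importances: np.ndarray,
    feature_names: list[str],
    family_of: dict[str, str] | None = None,
) -> ImportanceBreakdown:
    """Aggregate per-model Gini importances into family percentages.

    ``importances`` has one row per fitted model and one column per
    feature in ``feature_names``.  Unknown feature names are rejected.
    """
    family_of = FAMILY_OF if family_of is None else family_of
    importances = np.asarray(importances, dtype=float)
    if importances.ndim != 2 or importances.shape[1] != len(feature_names):
        raise ValueError("importances must be (n_models, n_features)")
    if np.any(importances < 0):
        raise ValueError("Gini importances must be nonnegative")
    unknown = [n for n in feature_names if n not in family_of]
    if unknown:
        raise ValueError(f"unknown feature names: {unknown}")

    mean_imp = importances.mean(axis=0)
    sd_imp = importances.std(axis=0, ddof=0)

    sums = {fam: 0.0 for fam in FAMILIES}
    for name, value in zip(feature_names, mean_imp):
        sums[family_of[name]] += float(value)
    total = sum(sums.values())
    if total <= 0:
        raise ValueError("all importances are zero")
    percent = {fam: 100.0 * v / total for fam, v in sums.items()}

    flagged = flag_unstable(sd_imp, names=feature_names)
    return ImportanceBreakdown(
        family_percent=percent,
        mean_importance=dict(zip(feature_names, mean_imp)),
        sd_importance=dict(zip(feature_names, sd_imp)),
        flagged_features=flagged,
    )
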