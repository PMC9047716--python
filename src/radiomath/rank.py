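"""Per-ROI random-forest regression protocol and area ranking.

For one brain area and one test score the protocol is: 20 random
80/20 train/test partitions of the subjects; per partition, feature
selection fitted on the training split only, then 100 random-forest
regressors (100 trees, depth <= 5, distinct seeds) fitted on the kept
features plus age; the partition's error is the mean hold-out MAE of
its models and the area's error the *median* over partitions (robust to
outlier partitions).  An age-only baseline run of the same protocol
quantifies the added value of the image features.

Per-model seeds are derived from (master seed, partition index, model
index) through ``numpy.random.SeedSequence``, so any result is exactly
reproducible from the master seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .select import DEFAULT_THRESHOLD_R2, decorrelate


@dataclass
class RankingConfig:
    """Protocol hyperparameters (defaults: the full published protocol)."""

    n_partitions: int = 20
    train_fraction: float = 0.8
    models_per_partition: int = 100
    trees: int = 100
    max_depth: int = 5
    threshold_r2: float = DEFAULT_THRESHOLD_R2
    #: "per-partition": selection fitted on each training split (no
    #: leakage; default).  "global": selection fitted once per area on
    #: all subjects before partitioning.
    selection_scope: str = "per-partition"
    seed: int = 0

    def validate(self, n_subjects: int) -> None:
        if self.selection_scope not in ("per-partition", "global"):
            raise ValueError("selection_scope must be 'per-partition' or 'global'")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if min(self.n_partitions, self.models_per_partition, self.trees, self.max_depth) < 1:
            raise ValueError("all protocol counts must be >= 1")
        n_test = n_subjects - int(np.floor(self.train_fraction * n_subjects))
        if n_test < 2:
            raise ValueError("test split smaller than 2 subjects; adjust train_fraction")


def scaled_down_config(seed: int = 0) -> RankingConfig:
    """Desk-scale protocol used by the simulation studies and demo runs.

    Same structure as the full protocol with fewer partitions, models,
    and trees; see the methods note for the rationale on problem sizes.
    """
    return RankingConfig(
        n_partitions=5, models_per_partition=2, trees=10, seed=seed
    )


@dataclass
class AreaRankingResult:
    roi_label: int
    partition_maes: np.ndarray
    median_mae: float
    baseline_mae: float | None = None
    importances: np.ndarray = field(default=None, repr=False)  # (models, features)
    feature_names: list[str] = field(default_factory=list, repr=False)
    kept_counts: list[int] = field(default_factory=list, repr=False)

    @property
    def improvement(self) -> float | None:
        if self.baseline_mae is None:
            return None
        return mae_improvement(self.baseline_mae, self.median_mae)


def mae(pred, actual) -> float:
    """Mean absolute error between predictions and actual scores."""
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if pred.size == 0 or pred.size != actual.size:
        raise ValueError("pred and actual must be equal-length and non-empty")
    return float(np.mean(np.abs(pred - actual)))


def mae_improvement(baseline: float, achieved: float) -> float:
    """Relative MAE reduction versus the baseline, in percent."""
    return 100.0 * (baseline - achieved) / baseline


def _model_seed(master: int, partition: int, model: int) -> int:
    return int(
        np.random.SeedSequence((master, partition, model)).generate_state(1)[0]
        % (2**31)
    )


def _partition_indices(n: int, config: RankingConfig, partition: int):
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, partition)))
    order = rng.permutation(n)
    n_train = int(np.floor(config.train_fraction * n))
    return order[:n_train], order[n_train:]


def rank_area(
    features: pd.DataFrame,
    y: np.ndarray,
    config: RankingConfig,
    roi_label: int = 0,
    select_features: bool = True,
) -> AreaRankingResult:
    """Run the full partition/model protocol for one area.

    ``features`` holds one row per subject, in catalog column order,
    with an ``age`` column appended; ``y`` the normalized target scores.
    Feature selection is fitted on each partition's training split only.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(features)
    if n != y.size:
        raise ValueError("feature rows and target length disagree")
    config.validate(n)

    names = list(features.columns)
    X_all = features.to_numpy(dtype=float)
    col_of = {name: i for i, name in enumerate(names)}

    partition_maes = np.empty(config.n_partitions)
    importances = np.zeros(
        (config.n_partitions * config.models_per_partition, len(names))
    )
    kept_counts = []

    global_kept = None
    if select_features and config.selection_scope == "global":
        global_kept = decorrelate(features, threshold_r2=config.threshold_r2).kept

    for p in range(config.n_partitions):
        tr, te = _partition_indices(n, config, p)
        if not select_features:
            kept = names
        elif global_kept is not None:
            kept = global_kept
        else:
            kept = decorrelate(
                features.iloc[tr], threshold_r2=config.threshold_r2
            ).kept
        kept_idx = [col_of[k] for k in kept]
        kept_counts.append(len([k for k in kept if k != "age"]))
        Xtr, Xte = X_all[np.ix_(tr, kept_idx)], X_all[np.ix_(te, kept_idx)]

        model_maes = np.empty(config.models_per_partition)
        for m in range(config.models_per_partition):
            forest = RandomForestRegressor(
                n_estimators=config.trees,
                max_depth=config.max_depth,
                random_state=_model_seed(config.seed, p, m),
            )
            forest.fit(Xtr, y[tr])
            model_maes[m] = mae(forest.predict(Xte), y[te])
            row = p * config.models_per_partition + m
            importances[row, kept_idx] = forest.feature_importances_
        partition_maes[p] = model_maes.mean()

    return AreaRankingResult(
        roi_label=int(roi_label),
        partition_maes=partition_maes,
        median_mae=float(np.median(partition_maes)),
        importances=importances,
        feature_names=names,
        kept_counts=kept_counts,
    )


def baseline_mae(age: np.ndarray, y: np.ndarray, config: RankingConfig) -> float:
    """Median hold-out MAE of the same protocol with age as sole input."""
    features = pd.DataFrame({"age": np.asarray(age, dtype=float)})
    result = rank_area(features, y, config, select_features=False)
    return result.median_mae


def rank_all(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    y: np.ndarray,
    config: RankingConfig,
) -> list[AreaRankingResult]:
    """Rank every ROI of a long-format feature table, best (lowest) first.

    ``features`` must carry ``subject_id`` and ``roi_label`` columns and
    one row per (subject, ROI); every ROI must cover every cohort
    subject.  Ties in median MAE break by ROI label.
    """
    y = np.asarray(y, dtype=float).ravel()
    subjects = list(cohort["subject_id"])
    age = cohort["age"].to_numpy(dtype=float)

    missing = []
    results = []
    base = baseline_mae(age, y, config)
    feature_cols = [c for c in features.columns if c not in ("subject_id", "roi_label")]
    for label, group in features.groupby("roi_label"):
        group = group.set_index("subject_id")
        if set(group.index) != set(subjects) or len(group) != len(subjects):
            missing.append(int(label))
            continue
        table = group.loc[subjects, feature_cols].reset_index(drop=True).copy()
        table["age"] = age
        res = rank_area(table, y, config, roi_label=int(label))
        res.baseline_mae = base
        results.append(res)
    if missing:
        raise ValueError(f"ROIs with missing subject rows: {missing}")
    results.sort(key=lambda r: (r.median_mae, r.roi_label))
    return results
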