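"""Random-forest MAE ranking protocol: error metric, planted and null
signals, determinism, and validation."""

import numpy as np
import pandas as pd
import pytest

from radiomath import (
    RankingConfig,
    baseline_mae,
    mae,
    mae_improvement,
    rank_all,
    rank_area,
)


def tiny_config(seed=0, **kw):
    kw.setdefault("n_partitions", 4)
    kw.setdefault("models_per_partition", 2)
    kw.setdefault("trees", 15)
    return RankingConfig(seed=seed, **kw)


def synthetic_cohort(n=60, seed=0):
    rng = np.random.default_rng(seed)
    age = rng.uniform(8, 12, n)
    return age, rng


class TestMae:
    def test_identity_is_zero(self):
        assert mae([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == 0.0

    def test_simple_arithmetic(self):
        assert mae([0.0, 0.0], [0.2, 0.4]) == pytest.approx(0.3)

    def test_constant_mean_predictor_equals_mean_absolute_deviation(self):
        rng = np.random.default_rng(1)
        y = rng.random(200)
        pred = np.full_like(y, y.mean())
        assert mae(pred, y) == pytest.approx(np.mean(np.abs(y - y.mean())))

    def test_empty_or_mismatched_rejected(self):
        with pytest.raises(ValueError):
            mae([], [])
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])


def test_mae_improvement_formula():
    assert mae_improvement(0.2, 0.1) == pytest.approx(50.0)
    assert mae_improvement(0.2, 0.2) == 0.0


def test_deterministic_feature_recovers_target_and_beats_baseline():
    """Target a noiseless function of one feature: the forest should
    drive the hold-out MAE far below the age-only baseline."""
    age, rng = synthetic_cohort(seed=2)
    x = rng.random(len(age))
    y = x  # deterministic, noise-free
    features = pd.DataFrame({"f1": x, "f2": rng.standard_normal(len(age))})
    features["age"] = age
    config = tiny_config(seed=2)
    result = rank_area(features, y, config)
    base = baseline_mae(age, y, config)
    assert result.median_mae < 0.25 * base
    assert result.median_mae < 0.05


def test_pure_noise_features_track_age_baseline():
    age, rng = synthetic_cohort(n=77, seed=3)
    y = np.clip(0.08 * (age - 8) + 0.15 * rng.standard_normal(len(age)), 0, 1)
    features = pd.DataFrame(
        rng.standard_normal((len(age), 10)), columns=[f"f{i}" for i in range(10)]
    )
    features["age"] = age
    config = tiny_config(seed=3)
    result = rank_area(features, y, config)
    base = baseline_mae(age, y, config)
    assert result.median_mae == pytest.approx(base, rel=0.25)


def test_same_seed_reproduces_result_exactly():
    age, rng = synthetic_cohort(seed=4)
    y = rng.random(len(age))
    features = pd.DataFrame({"f1": rng.standard_normal(len(age)), "age": age})
    r1 = rank_area(features, y, tiny_config(seed=4))
    r2 = rank_area(features, y, tiny_config(seed=4))
    assert np.array_equal(r1.partition_maes, r2.partition_maes)
    assert np.array_equal(r1.importances, r2.importances)
    r3 = rank_area(features, y, tiny_config(seed=5))
    assert not np.array_equal(r1.partition_maes, r3.partition_maes)


def test_median_is_median_of_partition_maes():
    age, rng = synthetic_cohort(seed=6)
    y = rng.random(len(age))
    features = pd.DataFrame({"f1": rng.standard_normal(len(age)), "age": age})
    r = rank_area(features, y, tiny_config(seed=6))
    assert r.median_mae == np.median(r.partition_maes)
    assert (r.partition_maes >= 0).all()


def test_importances_sum_to_one_per_model():
    """Normalization contract of impurity-decrease importances."""
    age, rng = synthetic_cohort(seed=7)
    y = np.clip(0.5 + 0.3 * rng.standard_normal(len(age)), 0, 1)
    features = pd.DataFrame(
        rng.standard_normal((len(age), 5)), columns=[f"f{i}" for i in range(5)]
    )
    features["age"] = age
    r = rank_area(features, y, tiny_config(seed=7))
    sums = r.importances.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_config_rejects_undersized_test_split():
    config = RankingConfig(train_fraction=0.95)
    with pytest.raises(ValueError, match="test split"):
        config.validate(20)


def test_rank_all_orders_by_median_mae_and_validates_coverage(null_feature_table, small_cohort):
    y = small_cohort["mf_norm"].to_numpy()
    config = tiny_config(seed=8)
    results = rank_all(null_feature_table, small_cohort, y, config)
    assert len(results) == null_feature_table["roi_label"].nunique()
    maes = [r.median_mae for r in results]
    assert maes == sorted(maes)
    assert len({r.baseline_mae for r in results}) == 1  # baseline shared

    broken = null_feature_table[
        ~(
            (null_feature_table.roi_label == 2)
            & (null_feature_table.subject_id == small_cohort.iloc[0]["subject_id"])
        )
    ]
    with pytest.raises(ValueError, match="missing subject rows"):
        rank_all(broken, small_cohort, y, config)


def test_single_roi_gives_single_result(null_feature_table, small_cohort):
    y = small_cohort["mf_norm"].to_numpy()
    one = null_feature_table[null_feature_table.roi_label == 1]
    results = rank_all(one, small_cohort, y, tiny_config(seed=9))
    assert len(results) == 1
    assert results[0].roi_label == 1
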