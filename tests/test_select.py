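"""Sequential correlation-based feature elimination."""

import numpy as np
import pandas as pd
import pytest

from radiomath import decorrelate


def literal_sequential_loop(df, threshold):
    """Independent oracle: the stated walk, written as the naive loop."""
    names = list(df.columns)
    kept = [n for n in names if df[n].std() > 0]
    i = 0
    while i < len(kept):
        survivor = [kept[j] for j in range(i + 1)]
        for later in kept[i + 1 :]:
            r = np.corrcoef(df[kept[i]], df[later])[0, 1]
            if r**2 <= threshold:
                survivor.append(later)
        kept = survivor
        i += 1
    return kept


def make_table(columns):
    return pd.DataFrame(columns)


def test_exact_duplicate_dropped_with_cause():
    rng = np.random.default_rng(0)
    f1 = rng.standard_normal(30)
    table = make_table({"f1": f1, "f2": 2.0 * f1, "f3": rng.standard_normal(30)})
    result = decorrelate(table, threshold_r2=0.8, protected=())
    assert result.kept == ["f1", "f3"]
    assert result.dropped == {"f2": "f1"}
    assert result.retention == pytest.approx(2 / 3)


def test_threshold_is_strict_both_kept_at_exactly_0_8():
    # build a pair with r^2 == 0.8 exactly: r = sqrt(0.8)
    n = 400
    rng = np.random.default_rng(1)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    e -= e.mean()
    e -= x * (x @ e) / (x @ x)  # orthogonalize
    e /= e.std()
    r = np.sqrt(0.8)
    y = r * x + np.sqrt(1 - r**2) * e
    table = make_table({"f1": x, "f2": y})
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    assert r2 == pytest.approx(0.8, abs=1e-12)
    # at the exact threshold the pair survives (removal needs r^2 strictly above)
    at = decorrelate(table, threshold_r2=r2, protected=())
    assert at.kept == ["f1", "f2"]
    below = decorrelate(table, threshold_r2=r2 - 1e-9, protected=())
    assert below.kept == ["f1"] and below.dropped == {"f2": "f1"}


def test_sequential_rule_matches_literal_loop_on_random_tables():
    rng = np.random.default_rng(2)
    for trial in range(8):
        base = rng.standard_normal((40, 4))
        mix = rng.standard_normal((4, 12))
        noise = 0.3 * rng.standard_normal((40, 12))
        table = pd.DataFrame(base @ mix + noise, columns=[f"f{i}" for i in range(12)])
        result = decorrelate(table, threshold_r2=0.8, protected=())
        assert result.kept == literal_sequential_loop(table, 0.8), trial


def test_idempotence():
    rng = np.random.default_rng(3)
    base = rng.standard_normal((40, 3))
    mix = rng.standard_normal((3, 10))
    table = pd.DataFrame(base @ mix + 0.2 * rng.standard_normal((40, 10)),
                         columns=[f"f{i}" for i in range(10)])
    first = decorrelate(table, protected=())
    second = decorrelate(table[first.kept], protected=())
    assert second.kept == first.kept
    assert second.dropped == {}


def test_catalog_order_dependence_is_real():
    """The walk is order dependent by design: with a correlated triple,
    whichever feature comes first absorbs the others."""
    rng = np.random.default_rng(4)
    a = rng.standard_normal(50)
    b = a + 0.1 * rng.standard_normal(50)
    c = rng.standard_normal(50)
    fwd = decorrelate(make_table({"a": a, "b": b, "c": c}), protected=())
    rev = decorrelate(make_table({"b": b, "a": a, "c": c}), protected=())
    assert fwd.kept == ["a", "c"]
    assert rev.kept == ["b", "c"]


def test_duplicated_blocks_collapse_to_one_per_block():
    rng = np.random.default_rng(5)
    blocks = 4
    cols = {}
    for b in range(blocks):
        x = rng.standard_normal(60)
        for r in range(3):
            cols[f"b{b}_r{r}"] = x + 1e-6 * rng.standard_normal(60)
    cols["indep"] = rng.standard_normal(60)
    result = decorrelate(pd.DataFrame(cols), protected=())
    assert len(result.kept) == blocks + 1


def test_constant_features_dropped_first_and_age_protected():
    rng = np.random.default_rng(6)
    table = make_table(
        {
            "f1": np.full(20, 3.0),
            "f2": rng.standard_normal(20),
            "age": rng.uniform(8, 12, 20),
        }
    )
    table["f3"] = table["age"] * 2.0  # perfectly correlated with age
    result = decorrelate(table[["f1", "f2", "f3", "age"]])
    assert result.dropped["f1"] == "constant"
    assert "age" in result.kept
    assert "f3" in result.kept  # age never causes a removal


def test_fewer_than_three_rows_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        decorrelate(pd.DataFrame({"f1": [1.0, 2.0], "f2": [2.0, 1.0]}))
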