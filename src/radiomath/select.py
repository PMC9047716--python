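"""Sequential correlation-based feature elimination.

Walking the catalog front to back (shape features first), each
still-kept feature removes every *later* feature whose squared Pearson
correlation with it exceeds the threshold strictly — correlated
features are assumed to share information, and the earlier one wins.
The walk order is part of the method's definition: permuting the
catalog can change the kept set.

Zero-variance columns are removed up front (cause ``"constant"``); the
age covariate is never a removal candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD_R2 = 0.8


@dataclass
class SelectionResult:
    kept: list[str]
    dropped: dict[str, str]  # dropped feature -> cause feature (or "constant")
    retention: float

    def __post_init__(self) -> None:
        assert not set(self.kept) & set(self.dropped)


def decorrelate(
    features: pd.DataFrame,
    threshold_r2: float = DEFAULT_THRESHOLD_R2,
    protected: tuple[str, ...] = ("age",),
) -> SelectionResult:
    """Run the sequential elimination on a feature table.

    ``features`` columns must already be in catalog order.  Requires at
    least 3 rows (pairwise correlation on fewer is vacuous).  A pair at
    exactly the threshold is kept: removal needs r^2 strictly above it.
    """
    if len(features) < 3:
        raise ValueError("decorrelate needs at least 3 rows")
    names = [c for c in features.columns if c not in protected]
    X = features[names].to_numpy(dtype=float)

    dropped: dict[str, str] = {}
    sd = X.std(axis=0)
    alive = []
    for idx, name in enumerate(names):
        if sd[idx] == 0:
            dropped[name] = "constant"
        else:
            alive.append(idx)

    if alive:
        Xa = X[:, alive]
        with np.errstate(invalid="ignore"):
            r2 = np.corrcoef(Xa, rowvar=False) ** 2
        kept_mask = np.ones(len(alive), dtype=bool)
        for a in range(len(alive)):
            if not kept_mask[a]:
                continue
            for b in range(a + 1, len(alive)):
                if kept_mask[b] and r2[a, b] > threshold_r2:
                    kept_mask[b] = False
                    dropped[names[alive[b]]] = names[alive[a]]
        kept = [names[alive[a]] for a in range(len(alive)) if kept_mask[a]]
    else:
        kept = []

    kept_all = kept + [p for p in protected if p in features.columns]
    return SelectionResult(
        kept=kept_all,
        dropped=dropped,
        retention=len(kept) / len(names) if names else 0.0,
    )
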