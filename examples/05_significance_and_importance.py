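"""Randomization-test significance and Gini-importance decomposition.

Continues the planted-signal setup: builds the noise distribution by
re-running the identical protocol on random features, assigns each
area a p-value, and decomposes the signal area's model importances by
feature family.
"""

import numpy as np
import pandas as pd

from radiomath import (SignalEffect, build_noise_distribution, default_cohort_spec,
                       default_phantom_spec, extract_all, family_importance,
                       generate_cohort, generate_phantom, normalize_scores,
                       rank_all, scaled_down_config, significance_table)

cohort, _ = normalize_scores(generate_cohort(default_cohort_spec(seed=4)))
spec = default_phantom_spec(
    n_rois=6, shape=(28, 28, 28), radius=3.2,
    signal_plan=[SignalEffect(1, "texture-contrast", 3.0, "mf")],
)
rng = np.random.default_rng(4)
features = pd.concat(
    [extract_all(*generate_phantom(r, spec, rng), subject_id=r["subject_id"])
     for _, r in cohort.iterrows()],
    ignore_index=True,
)
y = cohort["mf_norm"].to_numpy()
config = scaled_down_config(seed=4)
results = rank_all(features, cohort, y, config)

n_feat = int(np.median([np.median(r.kept_counts) for r in results]))
noise = build_noise_distribution(cohort, y, config, n_features=n_feat,
                                 n_replicates=30, seed=4)
print(f"noise distribution: mu {noise.mu:.3f}, sigma {noise.sigma:.4f} "
      f"({noise.n_replicates} replicates of {n_feat} random features)")

table = significance_table(results, noise)
print(table.to_string(index=False))

signal = next(r for r in results if r.roi_label == 1)
shares = family_importance(signal.importances, signal.feature_names).family_percent
print("\nROI 1 Gini importance by family (%):")
for fam, pct in sorted(shares.items(), key=lambda kv: -kv[1]):
    print(f"  {fam:10s} {pct:5.1f}")
print("\nTexture should dominate: the planted effect modulates the noise "
      "texture, and z << -2 marks the area as significant vs the noise null.")
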