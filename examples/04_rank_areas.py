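"""Rank brain areas by hold-out MAE of random-forest regressions.

Plants a texture-contrast signal in ROI 1 linked to Math fluency, ranks
all areas with the scaled-down protocol, and compares against the
age-only baseline.
"""

import numpy as np
import pandas as pd

from radiomath import (SignalEffect, default_cohort_spec, default_phantom_spec,
                       extract_all, generate_cohort, generate_phantom,
                       normalize_scores, rank_all, scaled_down_config)

cohort, _ = normalize_scores(generate_cohort(default_cohort_spec(seed=3)))
spec = default_phantom_spec(
    n_rois=6, shape=(28, 28, 28), radius=3.2,
    signal_plan=[SignalEffect(1, "texture-contrast", 3.0, "mf")],
)
rng = np.random.default_rng(3)
features = pd.concat(
    [extract_all(*generate_phantom(r, spec, rng), subject_id=r["subject_id"])
     for _, r in cohort.iterrows()],
    ignore_index=True,
)

results = rank_all(features, cohort, cohort["mf_norm"].to_numpy(),
                   scaled_down_config(seed=3))
print("area ranking (best first):")
for r in results:
    print(f"  ROI {r.roi_label}: median MAE {r.median_mae:.3f} "
          f"(baseline {r.baseline_mae:.3f}, improvement {r.improvement:.0f}%)")
print("\nROI 1 carries the planted signal, so its MAE should undercut the "
      "age-only baseline by far more than the noise-only areas.")
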