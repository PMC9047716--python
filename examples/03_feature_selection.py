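"""Sequential correlation-based feature elimination on a feature table.

Extracts features for a small phantom cohort, then removes features
with squared Pearson correlation above 0.8 against an earlier catalog
entry — shape features, listed first, win against correlated texture.
"""

import numpy as np
import pandas as pd

from radiomath import (decorrelate, default_cohort_spec, default_phantom_spec,
                       extract_all, generate_cohort, generate_phantom,
                       normalize_scores)
from radiomath.catalog import FAMILY_OF

cohort, _ = normalize_scores(generate_cohort(default_cohort_spec(seed=2)))
cohort = cohort.head(25)
spec = default_phantom_spec(n_rois=1, shape=(24, 24, 24), radius=6)
rng = np.random.default_rng(2)
rows = [extract_all(*generate_phantom(r, spec, rng), subject_id=r["subject_id"])
        for _, r in cohort.iterrows()]
features = pd.concat(rows, ignore_index=True).drop(columns=["subject_id", "roi_label"])

result = decorrelate(features, threshold_r2=0.8, protected=())
print(f"kept {len(result.kept)}/100 features (retention {100 * result.retention:.0f}%)")
fams = {}
for name in result.kept:
    fams[FAMILY_OF[name]] = fams.get(FAMILY_OF[name], 0) + 1
print("kept per family:", fams)
example = next(iter(result.dropped.items()))
print(f"example removal: {example[0]} dropped because it tracks {example[1]}")
print("\nThe retention fraction is the quantity reported per area "
      "(the study saw 39-81% on real data).")
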