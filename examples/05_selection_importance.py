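"""Stability assessment: repeated stepwise selection and shadow-feature importance.

Stepwise: over repeated threefold partitions of the years, the feature with
the largest |Pearson r| on each training set is tallied (Table-style
selection percentages).  Shadow-feature importance: every feature gets an
independently shuffled shadow copy, a random-forest regression scores all
columns by out-of-bag permutation importance, and binomial tests on the
"beats the best shadow" hit counts confirm or reject features.
"""

import numpy as np

from gridveg import (GridSpec, RFConfig, RunConfig, WorldConfig, boruta_repeat,
                     make_world, stepwise_cv_selection)
from gridveg.pipeline import feature_matrix, prepare_inputs

cfg = WorldConfig(seed=5, ndvi_grid=GridSpec(24, 24, 1.0), with_snow=False)
world = make_world(cfg)
ndvi, features, _ = prepare_inputs(world, RunConfig(world=cfg))
X, ids = feature_matrix(features, ndvi.years)

freqs = stepwise_cv_selection(X, ndvi.anomaly, ids, k=3, reps=100, seed=0)
print("stepwise selection (top 5 of", len(ids), "features, 300 fold fits):")
for s in freqs[:5]:
    print(f"  {s.feature_id:52s} {s.selection_pct:5.1f}%")

outcomes = boruta_repeat(X, ndvi.anomaly, ids, reps=3, max_runs=40,
                         rf_config=RFConfig(n_trees=150), seed=0)
print("\nshadow-feature importance (confirmed features, 3 repetitions):")
for o in outcomes:
    if o.confirmed_pct > 0:
        print(f"  {o.feature_id:52s} imp={o.mean_importance:5.2f} "
              f"confirmed {o.confirmed_pct:.0f}%")
print("planted driver:", world.truth.driver_feature_id)
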