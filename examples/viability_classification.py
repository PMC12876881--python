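"""Radiomics viability classification against fluorescence ground truth.

Simulates organoids in two texture regimes, derives HIGH/LOW viability
labels from a rendered live/dead fluorescence pair (the stain-based ground
truth), extracts the 32 texture features from the label-free OCM volume,
and cross-validates the gradient-boosted classifier.  The printed AUC is
the probability that a random high-viability organoid outscores a random
low-viability one.
"""

import numpy as np

from ocpam.classify import cross_validate, feature_importance, fit_full
from ocpam.radiomics import extract_feature_vector, FEATURE_NAMES
from ocpam.synthetic import generate_flm_pair, generate_organoid_timeseries
from ocpam.viability import score_organoids

X, y = [], []
for s in range(2):
    vols, masks, truth = generate_organoid_timeseries(
        40, days=(3, 5), class_mix={"WEAK": 1.0}, seed=10 + s,
        field_um=(300.0, 600.0, 600.0), initial_semiaxis_um=(10.0, 14.0, 0.15),
        viability_mix=0.5)
    # fluorescence-derived ground truth (50% cut-off on live pixel fraction)
    live, dead = generate_flm_pair(masks[0], truth, seed=20 + s)
    statuses = {vl.organoid_id: vl.status
                for vl in score_organoids(live, dead, masks[0])}
    # 32 texture features from the original (non-preprocessed) OCM volume
    for o in truth.organoids:
        if statuses.get(o.id) in ("HIGH", "LOW"):
            X.append(extract_feature_vector(vols[0], masks[0], o.id).as_array())
            y.append(statuses[o.id])
X, y = np.asarray(X), np.asarray(y)
print(f"{len(y)} organoids labelled by fluorescence: "
      f"{(y == 'HIGH').sum()} HIGH / {(y == 'LOW').sum()} LOW")

cv = cross_validate(X, y, k=10, seed=0)
print(f"10-fold CV mean AUC: {cv.mean_auc:.3f} "
      f"(fold range {min(cv.fold_aucs):.3f}-{max(cv.fold_aucs):.3f})")

model = fit_full(X, y, seed=0, feature_names=list(FEATURE_NAMES))
top = feature_importance(model)[:9]
print("nine most important texture features (gain share):")
for name, score in top:
    print(f"  {name}: {score:.3f}")
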