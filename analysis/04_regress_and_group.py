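#!/usr/bin/env python
"""Regress RMSD on the selected features and split segments into two groups.

Fits OLS of RMSD on the selected features (segments beyond 7 A RMSD
excluded as outliers), Ward-clusters the features on sign-aligned
correlation distances into two groups, and assigns every segment to the
group whose ablation perturbs its predicted RMSD more.
"""

import json
from pathlib import Path

import pandas as pd

from prosfold import statpipe
from prosfold.features import read_features_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"

df = read_features_tsv(ROOT / "features.tsv")
labels = statpipe.classify_all(df["rmsd"], 1.76, 4.13)
selection = statpipe.select_features(df, labels)
kept, dropped = statpipe.drop_collinear(df[selection.selected])
if dropped:
    print(f"dropped collinear features: {dropped}")

sub = df[["pros_id"] + kept]
model = statpipe.fit_regression(sub, df["rmsd"])
print(f"regression on {len(kept)} features, {model.n_used} segments "
      f"({int(model.outlier_mask.sum())} outliers beyond 7 A excluded): "
      f"R^2 = {model.r_squared:.3f}, r = {model.pearson_r:.3f}")
tvals = sorted(((f, t) for f, t in model.t_values.items() if f != "intercept"),
               key=lambda ft: -abs(ft[1]))
print("top contributions by |t|:", [(f, round(t, 2)) for f, t in tvals[:4]])

groups = statpipe.cluster_features(sub, df["rmsd"])
print(f"feature group 1: {groups.group1}")
print(f"feature group 2: {groups.group2}")

assignment = statpipe.assign_groups(model, groups, sub)
assignment["class"] = labels
assignment.to_csv(ROOT / "assignment.tsv", sep="\t", index=False)
(ROOT / "model.json").write_text(json.dumps(model.to_dict(), indent=1))
(ROOT / "groups.json").write_text(json.dumps(groups.to_dict(), indent=1))
print("segment group counts:",
      assignment.groupby(["class", "group"]).size().to_dict())
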