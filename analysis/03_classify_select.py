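#!/usr/bin/env python
"""Classify segments and screen features.

Classifies every segment at the published RMSD boundaries (1.76 / 4.13 A)
and reports which features separate the excellent from the poor class
under the Mann-Whitney U-test at p < 0.01.
"""

from pathlib import Path

import pandas as pd

from prosfold import statpipe
from prosfold.features import read_features_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"

df = read_features_tsv(ROOT / "features.tsv")
labels = statpipe.classify_all(df["rmsd"], 1.76, 4.13)
counts = pd.Series(labels).value_counts().to_dict()
print(f"class counts at (1.76, 4.13): {counts}")

selection = statpipe.select_features(df, labels)
frame = selection.to_frame().sort_values("p_ex_vs_poor")
frame.to_csv(ROOT / "selection.tsv", sep="\t", index=False)
print(f"{len(selection.selected)} features separate excellent from poor at "
      f"p < {selection.alpha}:")
print(frame[frame.selected][["feature", "p_ex_vs_poor"]].to_string(index=False))
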