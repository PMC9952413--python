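#!/usr/bin/env python
"""Generate the synthetic study cohort.

Forty conditionally folding segments under the two study conditions:
20 low-noise long helices with high planted model confidence (emulating
segments a structure predictor gets right) and 20 high-noise extended
coils with low confidence (segments it gets wrong).  Writes PDB files,
the segment table and the ground truth under results/synthetic/.
"""

import json
import sys
from pathlib import Path

from prosfold import synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

table = synthetic.write_study(OUT, seed=SEED)
truth = json.loads((OUT / "truth.json").read_text())
archetypes = {}
for info in truth.values():
    archetypes[info["archetype"]] = archetypes.get(info["archetype"], 0) + 1
print(f"wrote {len(truth)} segment pairs to {OUT} (seed {SEED})")
print(f"archetypes: {archetypes}")
print(f"segment table: {table}")
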