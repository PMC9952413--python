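#!/usr/bin/env python
"""Fetch the four worked-example inputs (network required).

Downloads the experimental complex structures 1pq1, 3i91, 2czy, 4rjf from
RCSB and the matching predicted monomeric models (UniProt O54918, Q9HC52,
Q13127, P38936) from AlphaFold DB into data/worked_examples/, which the
worked-example acceptance test reads.  The library itself never touches
the network; this helper exists so the per-segment checks against the
published values can be run where the data are reachable.

Note the model files are versioned upstream; confidence values can drift
slightly between model versions.
"""

import sys
import urllib.request
from pathlib import Path

PDB_IDS = ["1pq1", "3i91", "2czy", "4rjf"]
UNIPROT_ACS = ["O54918", "Q9HC52", "Q13127", "P38936"]

RCSB = "https://files.rcsb.org/download/{pdb}.pdb"
AFDB = "https://alphafold.ebi.ac.uk/files/AF-{acc}-F1-model_v4.pdb"

OUT = Path(__file__).resolve().parent.parent / "data" / "worked_examples"


def fetch(url: str, dest: Path) -> None:
    if dest.exists():
        print(f"have {dest.name}")
        return
    print(f"fetching {url}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    try:
        for pdb in PDB_IDS:
            fetch(RCSB.format(pdb=pdb), OUT / f"{pdb}.pdb")
        for acc in UNIPROT_ACS:
            fetch(AFDB.format(acc=acc), OUT / f"AF-{acc}-F1-model.pdb")
    except OSError as exc:
        print(f"download failed: {exc}", file=sys.stderr)
        return 1
    print(f"done; files in {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
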