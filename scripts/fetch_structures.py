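#!/usr/bin/env python
"""Download the deposited experimental structures used by the reproduction tests.

The library itself only reads local paths; this helper documents the
accessions and fetches them into ``data/structures/`` (network required):

  9FP6 - activated NbNRC2 hexameric resistosome (cryo-EM)
  8RFH - resting-state NbNRC2 homodimer
  6J5T - AtZAR1 pentameric resistosome
  7XE0 - TmSr35 pentameric resistosome (optional comparison)

Predicted-model coordinate files are distributed by their authors as a
separate model deposit and must be placed manually as
``data/structures/af3_nbnrc2_hexamer.cif`` and
``data/structures/af3_atzar1_pentamer.cif``.
"""

import sys
import urllib.request
from pathlib import Path

PDB_IDS = ["9fp6", "8rfh", "6j5t", "7xe0"]
URL = "https://files.rcsb.org/download/{pdb_id}.cif"
DEST = Path(__file__).resolve().parents[1] / "data" / "structures"


def main() -> int:
    DEST.mkdir(parents=True, exist_ok=True)
    status = 0
    for pdb_id in PDB_IDS:
        target = DEST / f"{pdb_id}.cif"
        if target.exists():
            print(f"{target} already present")
            continue
        url = URL.format(pdb_id=pdb_id)
        try:
            print(f"fetching {url} ...")
            urllib.request.urlretrieve(url, target)
        except OSError as exc:
            print(f"  failed: {exc}", file=sys.stderr)
            status = 1
    return status


if __name__ == "__main__":
    raise SystemExit(main())
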