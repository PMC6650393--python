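#!/usr/bin/env python
"""Fetch the calmodulin PDB entries used by the reference-value checks.

Downloads 1CLL (holo, X-ray), 2L53 (target-bound apo, NMR) and 1DMO
(apo, NMR) from RCSB into tests/data/pdb/.  These entries are not
redistributed with the package; without them the reference-structure
acceptance tests report failure with a pointer to this script.

Usage: python scripts/fetch_pdb.py [--dest DIR]
"""

import argparse
import sys
import urllib.request
from pathlib import Path

ENTRIES = ("1CLL", "2L53", "1DMO")
URL = "https://files.rcsb.org/download/{}.pdb"


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dest", default=None,
                    help="target directory (default: tests/data/pdb)")
    args = ap.parse_args()
    dest = Path(args.dest) if args.dest else \
        Path(__file__).resolve().parent.parent / "tests" / "data" / "pdb"
    dest.mkdir(parents=True, exist_ok=True)
    for pdb_id in ENTRIES:
        out = dest / f"{pdb_id}.pdb"
        if out.exists():
            print(f"{out} already present, skipping")
            continue
        url = URL.format(pdb_id)
        print(f"fetching {url} -> {out}")
        try:
            urllib.request.urlretrieve(url, out)
        except OSError as exc:
            print(f"error: could not fetch {pdb_id}: {exc}", file=sys.stderr)
            return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
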