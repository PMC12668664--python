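#!/usr/bin/env python
"""Download the deposited coordinate files used by the accession-based
regression checks (network required; never run by the test suite itself).

Files land under data/structures/ as mmCIF. The regression test in
tests/test_acceptance.py runs its deposited-structure checks only against
these local files and reports exactly which are missing otherwise.

Usage:  python scripts/fetch_structures.py [--dest data/structures]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ["9D73", "9D74", "8TQ6", "1EFX", "3VH8"]
URL = "https://files.rcsb.org/download/{}.cif"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", default="data/structures", type=Path)
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    failures = 0
    for acc in ACCESSIONS:
        target = args.dest / f"{acc}.cif"
        if target.exists():
            print(f"{acc}: already present")
            continue
        try:
            print(f"{acc}: downloading ...")
            urllib.request.urlretrieve(URL.format(acc), target)
        except OSError as exc:
            print(f"{acc}: FAILED ({exc})", file=sys.stderr)
            failures += 1
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
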