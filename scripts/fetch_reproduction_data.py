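#!/usr/bin/env python
"""Fetch the deposited inputs for the structure-reproduction tests.

Downloads coordinate files (PDB 7fse, 7fsf, 4ddu, 4ddt, 3oiy, 3p4x) from
RCSB and the two full-length reverse gyrase sequences (UniProt B7IEV8 plus
the engineered minimal-latch construct's parent Q56312) into
``data/reproduction/``. Requires network access; the test suite skips the
reproduction checks when this directory is absent.

Usage: python scripts/fetch_reproduction_data.py [--dest data/reproduction]
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

PDB_IDS = ["7fse", "7fsf", "4ddu", "4ddt", "3oiy", "3p4x"]
UNIPROT_IDS = ["B7IEV8", "Q56312"]


def fetch(url: str, dest: Path) -> None:
    print(f"  {url} -> {dest}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path, default=Path("data/reproduction"))
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for code in PDB_IDS:
        out = args.dest / f"{code}.pdb"
        if not out.exists():
            fetch(f"https://files.rcsb.org/download/{code.upper()}.pdb", out)
    fastas = []
    for acc in UNIPROT_IDS:
        out = args.dest / f"{acc}.fasta"
        if not out.exists():
            fetch(f"https://rest.uniprot.org/uniprotkb/{acc}.fasta", out)
        fastas.append(out.read_text())
    pair = args.dest / "homolog_pair.fasta"
    if not pair.exists():
        # the engineered construct: parent sequence minus residues 395-455
        import re

        def parse(text):
            lines = text.splitlines()
            return lines[0], "".join(lines[1:])

        hdr_b, seq_b = parse(fastas[0])
        hdr_q, seq_q = parse(fastas[1])
        minlatch = seq_q[:394] + seq_q[455:]
        pair.write_text(
            f"{hdr_b}\n{seq_b}\n>minimal_latch_construct\n{minlatch}\n"
        )
    print("done")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
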