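#!/usr/bin/env python
"""Optional helper: download GenBank sequence regions as FASTA.

The talocus library performs no network access itself; locus regions are
analysed from local FASTA files.  This standalone script fetches accession
ranges from NCBI E-utilities for users who want to build a panel of real
plasmid regions, e.g.:

    python scripts/fetch_regions.py --out panel_dir \\
        ACC12345:1598-1974 ACC67890:3644-4019

Each argument is ACCESSION:START-END (1-based inclusive; START > END denotes
the minus strand, fetched as the plus-strand window — strand handling is done
downstream by the library's GenBank-style range convention).  Requires
network access; not exercised by the test suite.
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str, start: int, end: int) -> str:
    lo, hi = min(start, end), max(start, end)
    params = urllib.parse.urlencode(
        {
            "db": "nuccore",
            "id": accession,
            "rettype": "fasta",
            "retmode": "text",
            "seq_start": lo,
            "seq_stop": hi,
        }
    )
    with urllib.request.urlopen(f"{EUTILS}?{params}", timeout=60) as resp:
        return resp.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("regions", nargs="+", help="ACCESSION:START-END")
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--pad", type=int, default=100,
                        help="extra bp fetched on both sides")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for region in args.regions:
        acc, _, rng = region.partition(":")
        a, _, b = rng.partition("-")
        lo, hi = sorted((int(a), int(b)))
        fasta = fetch(acc, max(1, lo - args.pad), hi + args.pad)
        path = args.out / f"{acc}_{lo}_{hi}.fasta"
        path.write_text(fasta)
        print(f"wrote {path}")
        time.sleep(0.4)  # E-utilities rate courtesy


if __name__ == "__main__":
    main()
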