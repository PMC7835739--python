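#!/usr/bin/env python
"""One-time fetch of the PKM transcript protein sequences from Ensembl.

Downloads the translated sequences of the five transcripts analyzed by
the annotation module (PKM1, PKM2 and the three minor isoforms) from the
Ensembl REST service and writes them to ``data/pkm_proteins.fa`` at the
repository root. Requires network access; the annotation checks that
depend on these reference sequences report their absence until this has
been run once.

Usage: python scripts/fetch_protein_fixtures.py [--out data/pkm_proteins.fa]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

TRANSCRIPTS = {
    "ENST00000319622": "PKM1",
    "ENST00000335181": "PKM2",
    "ENST00000561609": "PKM-609",
    "ENST00000389093": "PKM-093",
    "ENST00000568883": "PKM-883",
}

URL = "https://rest.ensembl.org/sequence/id/{tid}?type=protein;content-type=text/x-fasta"


def fetch(tid: str) -> str:
    req = urllib.request.Request(URL.format(tid=tid), headers={"User-Agent": "splice-prognosis"})
    with urllib.request.urlopen(req, timeout=30) as resp:
        return resp.read().decode()


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    default_out = Path(__file__).resolve().parent.parent / "data" / "pkm_proteins.fa"
    parser.add_argument("--out", type=Path, default=default_out)
    args = parser.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    chunks = []
    for tid, label in TRANSCRIPTS.items():
        try:
            fasta = fetch(tid)
        except Exception as exc:  # noqa: BLE001
            print(f"failed to fetch {tid} ({label}): {exc}", file=sys.stderr)
            return 1
        header, _, body = fasta.partition("\n")
        chunks.append(f">{tid} {label}\n{body.strip()}\n")
        print(f"fetched {tid} ({label}): {sum(len(l) for l in body.split())} aa")
    args.out.write_text("".join(chunks))
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
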