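"""One-time download of the deposited cytochrome-b sequences.

Fetches GenBank records KU588290-KU588384 (95 turtle-dove cytochrome-b
sequences, 892 bp) from NCBI E-utilities and writes them, uppercased, to
``data/cytb_KU588290-KU588384.fasta`` relative to the repository root.
Requires network access; the sequences are public but are not
redistributed with this repository.

Usage: python scripts/fetch_cytb.py
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = [f"KU588{i}" for i in range(290, 385)]
OUT = Path(__file__).resolve().parent.parent / "data" / "cytb_KU588290-KU588384.fasta"
EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&rettype=fasta&retmode=text&id={ids}"
)


def main() -> int:
    url = EFETCH.format(ids=",".join(ACCESSIONS))
    print(f"fetching {len(ACCESSIONS)} records from NCBI ...", file=sys.stderr)
    try:
        with urllib.request.urlopen(url, timeout=120) as response:
            text = response.read().decode()
    except OSError as err:
        print(f"download failed: {err}", file=sys.stderr)
        return 1
    n_records = text.count(">")
    if n_records != len(ACCESSIONS):
        print(f"expected {len(ACCESSIONS)} records, got {n_records}", file=sys.stderr)
        return 1
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(text.upper())
    print(f"wrote {OUT}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
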