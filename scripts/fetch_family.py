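#!/usr/bin/env python
"""Download the 13 mature human RNaseA sequences from UniProt (network needed).

Fetches each accession's flat-text entry, cuts the signal peptide using the
annotated SIGNAL feature, and writes ``data/hrnasea13_mature.fasta`` used by
the full-family acceptance test.  Run once from the repository root:

    python scripts/fetch_family.py
"""

from __future__ import annotations

import re
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = [
    "P07998",  # RNase1
    "P10153",  # RNase2
    "P12724",  # RNase3
    "P34096",  # RNase4
    "P03950",  # RNase5
    "Q93061",  # RNase6
    "Q9H1E1",  # RNase7
    "Q8TDE3",  # RNase8
    "P60153",  # RNase9
    "Q5GAN6",  # RNase10
    "Q5GAN5",  # RNase11
    "Q5GAN4",  # RNase12
    "Q5GAN3",  # RNase13
]

OUT = Path(__file__).resolve().parent.parent / "data" / "hrnasea13_mature.fasta"


def fetch_entry(accession: str) -> str:
    url = f"https://rest.uniprot.org/uniprotkb/{accession}.txt"
    with urllib.request.urlopen(url, timeout=60) as handle:
        return handle.read().decode()


def mature_sequence(flat_text: str) -> str:
    signal_end = 0
    match = re.search(r"^FT\s+SIGNAL\s+(\d+)\.\.(\d+)", flat_text, re.MULTILINE)
    if match:
        signal_end = int(match.group(2))
    lines = flat_text.splitlines()
    seq_lines = []
    in_seq = False
    for line in lines:
        if line.startswith("SQ"):
            in_seq = True
            continue
        if in_seq:
            if line.startswith("//"):
                break
            seq_lines.append(line.replace(" ", ""))
    full = "".join(seq_lines)
    if not full:
        raise RuntimeError("no sequence block found")
    return full[signal_end:]


def main() -> None:
    OUT.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for accession in ACCESSIONS:
        sys.stderr.write(f"fetching {accession}...\n")
        entry = fetch_entry(accession)
        mature = mature_sequence(entry)
        records.append((accession, mature))
    with open(OUT, "w") as fh:
        for accession, seq in records:
            fh.write(f">{accession} mature chain\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    print(f"wrote {OUT} ({len(records)} records)")


if __name__ == "__main__":
    main()
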