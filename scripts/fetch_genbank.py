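"""Fetch the published trnT-F GenBank records for full-scale validation.

The desk-scale test and acceptance suites are self-contained; only the
reproduction of the published per-species amplicon lengths needs the real
records (accessions JQ041821-JQ041881 plus related entries for taxa
sequenced elsewhere).  Those records are not redistributed with the
package; this helper materialises them under ``data/genbank/`` for anyone
with network access:

    python scripts/fetch_genbank.py [--out data/genbank]

Requires outbound HTTPS to NCBI eutils.
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

#: The study's own submissions.
ACCESSION_RANGE = ("JQ041821", "JQ041881")


def accessions() -> list[str]:
    prefix = ACCESSION_RANGE[0][:2]
    lo = int(ACCESSION_RANGE[0][2:])
    hi = int(ACCESSION_RANGE[1][2:])
    return [f"{prefix}{i:06d}" for i in range(lo, hi + 1)]


def fetch(ids: list[str], rettype: str = "fasta") -> str:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": ",".join(ids), "rettype": rettype, "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=60) as resp:
        return resp.read().decode()


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="data/genbank")
    args = parser.parse_args(argv)
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)

    ids = accessions()
    chunks = [ids[i : i + 20] for i in range(0, len(ids), 20)]
    fasta_parts, gb_parts = [], []
    for chunk in chunks:
        fasta_parts.append(fetch(chunk, "fasta"))
        time.sleep(0.4)  # eutils rate courtesy
        gb_parts.append(fetch(chunk, "gb"))
        time.sleep(0.4)
    (outdir / "trntf_records.fasta").write_text("".join(fasta_parts))
    (outdir / "trntf_records.gb").write_text("".join(gb_parts))
    print(f"wrote {len(ids)} records to {outdir}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
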