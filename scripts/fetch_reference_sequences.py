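#!/usr/bin/env python
"""One-time network fetch of the six public Fox protein records used by the
published-identity checks (optional; the package itself never needs network).

Downloads from NCBI via Entrez and writes one FASTA per record into
``data/reference_fox_proteins/``:

    human_FOXJ1        Homo sapiens FOXJ1 (RefSeq protein)
    mouse_FoxJ1        Mus musculus Foxj1 (RefSeq protein)
    mouse_FoxJ2        Mus musculus Foxj2 (RefSeq protein)
    mouse_FoxN3        Mus musculus Foxn3 (RefSeq protein)
    spurpuratus_FoxJ1  Strongylocentrotus purpuratus foxJ1 (RefSeq protein)
    placozoa_H4_FoxJ1  Placozoa sp. H4 foxJ1, translated CDS of GenBank
                       nucleotide accession JX569795

Inspect the downloaded headers before use: gene-symbol queries can return
isoforms or re-annotated models, and the identity checks assume the
canonical full-length protein of each gene.

Usage:
    python scripts/fetch_reference_sequences.py --email you@example.org
"""

from __future__ import annotations

import argparse
import sys
import time
from pathlib import Path

from Bio import Entrez, SeqIO

OUT_DIR = Path(__file__).parent.parent / "data" / "reference_fox_proteins"

PROTEIN_QUERIES = {
    "human_FOXJ1": 'FOXJ1[Gene Name] AND "Homo sapiens"[Organism] AND srcdb_refseq[PROP]',
    "mouse_FoxJ1": 'Foxj1[Gene Name] AND "Mus musculus"[Organism] AND srcdb_refseq[PROP]',
    "mouse_FoxJ2": 'Foxj2[Gene Name] AND "Mus musculus"[Organism] AND srcdb_refseq[PROP]',
    "mouse_FoxN3": 'Foxn3[Gene Name] AND "Mus musculus"[Organism] AND srcdb_refseq[PROP]',
    "spurpuratus_FoxJ1": (
        'foxj1[Gene Name] AND "Strongylocentrotus purpuratus"[Organism] '
        "AND srcdb_refseq[PROP]"
    ),
}

PLACOZOA_NUCLEOTIDE_ACCESSION = "JX569795"


def fetch_protein(query: str) -> SeqIO.SeqRecord:
    with Entrez.esearch(db="protein", term=query, retmax=5) as handle:
        result = Entrez.read(handle)
    ids = result["IdList"]
    if not ids:
        raise RuntimeError(f"no protein record found for query: {query}")
    with Entrez.efetch(db="protein", id=ids[0], rettype="fasta", retmode="text") as handle:
        return next(SeqIO.parse(handle, "fasta"))


def fetch_placozoa_translation() -> SeqIO.SeqRecord:
    with Entrez.efetch(
        db="nuccore",
        id=PLACOZOA_NUCLEOTIDE_ACCESSION,
        rettype="fasta_cds_aa",
        retmode="text",
    ) as handle:
        return next(SeqIO.parse(handle, "fasta"))


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="Contact email required by NCBI Entrez.")
    args = parser.parse_args()
    Entrez.email = args.email

    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for name, query in PROTEIN_QUERIES.items():
        record = fetch_protein(query)
        path = OUT_DIR / f"{name}.fasta"
        SeqIO.write(record, path, "fasta")
        print(f"{name}: {record.id} ({len(record.seq)} aa) -> {path}")
        time.sleep(0.4)  # NCBI rate limit

    record = fetch_placozoa_translation()
    path = OUT_DIR / "placozoa_H4_FoxJ1.fasta"
    SeqIO.write(record, path, "fasta")
    print(f"placozoa_H4_FoxJ1: {record.id} ({len(record.seq)} aa) -> {path}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
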