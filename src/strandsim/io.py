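"""FASTA/FASTQ interchange and run manifests.

Encoded strand libraries are written as FASTA with the decimal origin index
as record id (parity strands carry a ``parity`` description); noisy read
sets can be emitted as FASTQ with placeholder qualities for interoperability
with standard read-processing tools.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import EncodedStrand


def write_library_fasta(strands: Sequence[EncodedStrand], path: str) -> None:
    records = [
        SeqRecord(
            Seq(s.dna),
            id=str(s.origin_index),
            description="parity" if s.is_parity else "",
        )
        for s in strands
    ]
    SeqIO.write(records, path, "fasta")


def read_library_fasta(path: str) -> list[EncodedStrand]:
    strands = []
    for rec in SeqIO.parse(path, "fasta"):
        strands.append(
            EncodedStrand(
                dna=str(rec.seq).upper(),
                origin_index=int(rec.id),
                is_parity="parity" in rec.description,
            )
        )
    return strands


def write_reads_fastq(reads: Iterable[str], path: str) -> None:
    records = []
    for i, dna in enumerate(reads):
        rec = SeqRecord(Seq(dna), id=f"read_{i}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(dna)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path: str) -> list[tuple[str, str]]:
    """(read id, sequence) pairs; malformed records are the parser's concern."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def spec_fingerprint(params: dict) -> str:
    """Stable hash of the per-run parameter record, for the manifest."""
    blob = json.dumps(params, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
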