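"""Domain types shared across the encode/decode pipeline.

DNA sequences are plain Python strings over the uppercase alphabet
``{A, C, G, T}``; byte blocks are ``bytes``. The dataclasses below carry the
structural bookkeeping: which packet a chunk belongs to, the global strand
index prepended to every strand, and the ground-truth snapshots that probes
record during encoding for later error accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .rs import DecodeStatus

DNA_ALPHABET = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(DNA_ALPHABET)}


def validate_dna(seq: str) -> str:
    """Return ``seq`` unchanged if it is a valid uppercase DNA string."""
    if any(c not in _BASE_TO_INT for c in seq):
        bad = sorted({c for c in seq if c not in _BASE_TO_INT})
        raise ValueError(f"invalid DNA characters: {bad}")
    return seq


@dataclass
class BaseSequence:
    """One strand-sized chunk of byte payload, before indexing."""

    payload: bytes
    packet_id: int
    position_in_packet: int
    is_parity: bool = False


@dataclass
class IndexedSequence:
    """A base-sequence with its global strand index attached.

    The serialized form is ``index_width`` big-endian index bytes followed by
    the payload; this whole byte string is what the inner stages protect.
    """

    index: int
    index_width: int
    payload: bytes
    is_parity: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.index < 256 ** self.index_width):
            raise ValueError(
                f"index {self.index} does not fit in {self.index_width} bytes"
            )

    def serialize(self) -> bytes:
        return self.index.to_bytes(self.index_width, "big") + self.payload

    @classmethod
    def deserialize(cls, raw: bytes, index_width: int) -> "IndexedSequence":
        if len(raw) < index_width:
            raise ValueError("byte string shorter than index width")
        return cls(
            index=int.from_bytes(raw[:index_width], "big"),
            index_width=index_width,
            payload=raw[index_width:],
        )


@dataclass
class Packet:
    """The scope of one outer code: a group of equal-length base-sequences."""

    packet_id: int
    data_sequences: list[BaseSequence]
    parity_sequences: list[BaseSequence] = field(default_factory=list)


@dataclass
class EncodedStrand:
    """A fully encoded DNA strand with its ground-truth identity."""

    dna: str
    origin_index: int
    is_parity: bool = False
    truth_snapshots: dict[str, object] = field(default_factory=dict)


@dataclass
class DecodeOutcome:
    """Result of decoding one strand (or one consolidated cluster)."""

    status: DecodeStatus
    recovered: Optional[IndexedSequence] = None
    score: float = 0.0
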