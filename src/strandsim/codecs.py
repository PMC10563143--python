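"""Concrete pipeline stages: randomizer, inner/outer Reed-Solomon,
binary-to-DNA transcoders, and functional-site affixes.

Stages come in three single-strand categories, mirroring how DNA storage
codecs are composed in practice:

* **binary transformation** — byte-to-byte maps applied before the data is
  represented as DNA (whitening, inner error correction);
* **transcoding** — the single stage that turns bytes into a DNA string
  (and back); exactly one per pipeline;
* **functional site encoding** — DNA affixes (e.g. PCR primer regions) that
  carry no payload information.

The cross-strand outer code lives here too (`outer_rs_encode` /
`outer_rs_decode`): a column-wise Reed-Solomon code where byte ``j`` of every
strand in a packet forms one codeword, so whole-strand dropouts become
erasures and silently corrupted strands become errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import edlib

from .rs import DecodeStatus, RSConfig, rs_decode, rs_encode
from .types import Packet, BaseSequence, validate_dna


class StageCategory(Enum):
    BINARY_TRANSFORMATION = "BinaryTransformation"
    TRANSCODING = "Transcoding"
    FUNCTIONAL_SITE_ENCODING = "FunctionalSiteEncoding"


class Stage:
    """Base class for single-strand pipeline stages."""

    category: StageCategory
    name: str = "stage"


class BinaryStage(Stage):
    category = StageCategory.BINARY_TRANSFORMATION

    def encode(self, data: bytes) -> bytes:
        raise NotImplementedError

    def decode(self, data: bytes) -> tuple[Optional[bytes], DecodeStatus]:
        raise NotImplementedError


class TranscodeStage(Stage):
    category = StageCategory.TRANSCODING

    def encode(self, data: bytes) -> str:
        raise NotImplementedError

    def decode(self, dna: str) -> tuple[Optional[bytes], DecodeStatus]:
        raise NotImplementedError


class SiteStage(Stage):
    category = StageCategory.FUNCTIONAL_SITE_ENCODING

    def encode(self, dna: str) -> str:
        raise NotImplementedError

    def decode(self, dna: str) -> tuple[Optional[str], DecodeStatus]:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# randomizer


def _xorshift64star_keystream(seed: int, n: int) -> bytes:
    """Byte-wise keystream from an xorshift64* generator (top byte of each
    64-bit output). A zero seed is remapped to a fixed non-zero constant."""
    mask = (1 << 64) - 1
    x = seed & mask
    if x == 0:
        x = 0x9E3779B97F4A7C15
    out = bytearray()
    while len(out) < n:
        x ^= x >> 12
        x = (x ^ (x << 25)) & mask
        x ^= x >> 27
        word = (x * 0x2545F4914F6CDD1D) & mask
        out += word.to_bytes(8, "big")
    return bytes(out[:n])


def randomize(data: bytes, seed: int) -> bytes:
    """XOR ``data`` with a seeded keystream; self-inverse for the same seed."""
    ks = _xorshift64star_keystream(seed, len(data))
    return bytes(a ^ b for a, b in zip(data, ks))


class Randomizer(BinaryStage):
    """Whitens payload bytes so runs of identical bytes do not translate into
    low-complexity DNA. Involutory: decode re-applies the same XOR."""

    name = "randomize"

    def __init__(self, seed: int = 0xD5A) -> None:
        self.seed = seed

    def encode(self, data: bytes) -> bytes:
        return randomize(data, self.seed)

    def decode(self, data: bytes) -> tuple[bytes, DecodeStatus]:
        return randomize(data, self.seed), DecodeStatus.SUCCESS


class InnerRS(BinaryStage):
    """Per-strand Reed-Solomon: appends ``n_parity`` bytes to the serialized
    index+payload so byte errors within one strand can be corrected."""

    name = "inner_rs"

    def __init__(self, cfg: RSConfig) -> None:
        self.cfg = cfg

    def encode(self, data: bytes) -> bytes:
        if len(data) != self.cfg.n_data:
            raise ValueError(
                f"inner RS expects {self.cfg.n_data} bytes, got {len(data)}"
            )
        return rs_encode(data, self.cfg)

    def decode(self, data: bytes) -> tuple[Optional[bytes], DecodeStatus]:
        if len(data) != self.cfg.n_total:
            return None, DecodeStatus.DETECTED_FAILURE
        res = rs_decode(data, self.cfg)
        return res.data, res.status


# ---------------------------------------------------------------------------
# transcoders

_BYTE_TO_DNA = [
    "".join("ACGT"[(b >> shift) & 3] for shift in (6, 4, 2, 0)) for b in range(256)
]
_PAIR_TO_VAL = {b: i for i, b in enumerate("ACGT")}


def transcode_2bit(data: bytes) -> str:
    """Map consecutive 2-bit groups (MSB first) to bases: 00→A 01→C 10→G 11→T."""
    return "".join(_BYTE_TO_DNA[b] for b in data)


def transcode_2bit_inverse(dna: str) -> bytes:
    if len(dna) % 4 != 0:
        raise ValueError("DNA length must be a multiple of 4 bases")
    out = bytearray()
    for i in range(0, len(dna), 4):
        b = 0
        for c in dna[i : i + 4]:
            b = (b << 2) | _PAIR_TO_VAL[c]
        out.append(b)
    return bytes(out)


class TwoBitTranscoder(TranscodeStage):
    """Dense 2 bits/base transcoder (no run-length constraints)."""

    name = "transcode_2bit"

    def encode(self, data: bytes) -> str:
        return transcode_2bit(data)

    def decode(self, dna: str) -> tuple[Optional[bytes], DecodeStatus]:
        if len(dna) % 4 != 0 or any(c not in _PAIR_TO_VAL for c in dna):
            return None, DecodeStatus.DETECTED_FAILURE
        return transcode_2bit_inverse(dna), DecodeStatus.SUCCESS


def _rot3_digit_width(n_bytes: int) -> int:
    # smallest d with 3**d >= 2**(8*n_bytes), computed exactly
    if n_bytes == 0:
        return 0
    d = math.ceil(n_bytes * 8 * math.log(2) / math.log(3))
    while 3**d < 2 ** (8 * n_bytes):
        d += 1
    while d > 0 and 3 ** (d - 1) >= 2 ** (8 * n_bytes):
        d -= 1
    return d


def transcode_rot3(data: bytes) -> str:
    """Base-3 rotation transcoder: the byte block is read as one big-endian
    integer, written as base-3 digits, and each digit picks one of the three
    bases that differ from the previously emitted base (previous base starts
    as an implicit 'A'). The output therefore never repeats a base."""
    width = _rot3_digit_width(len(data))
    value = int.from_bytes(data, "big")
    digits = [0] * width
    for i in range(width - 1, -1, -1):
        value, digits[i] = divmod(value, 3)
    prev = "A"
    out = []
    for d in digits:
        candidates = [b for b in "ACGT" if b != prev]
        prev = candidates[d]
        out.append(prev)
    return "".join(out)


def transcode_rot3_inverse(dna: str) -> bytes:
    validate_dna(dna)
    n_bytes = int(len(dna) * math.log(3) / (8 * math.log(2))) + 1
    while n_bytes > 0 and _rot3_digit_width(n_bytes) > len(dna):
        n_bytes -= 1
    if _rot3_digit_width(n_bytes) != len(dna):
        raise ValueError(f"{len(dna)} digits is not a valid rot3 block length")
    prev = "A"
    value = 0
    for c in dna:
        if c == prev:
            raise ValueError("repeated adjacent base: not a rot3 codeword")
        candidates = [b for b in "ACGT" if b != prev]
        value = value * 3 + candidates.index(c)
        prev = c
    if value >= 2 ** (8 * n_bytes):
        raise ValueError("digit value out of range: not a rot3 codeword")
    return value.to_bytes(n_bytes, "big")


class Rot3Transcoder(TranscodeStage):
    """Homopolymer-free transcoder at log2(3) ≈ 1.585 bits/base."""

    name = "transcode_rot3"

    def encode(self, data: bytes) -> str:
        return transcode_rot3(data)

    def decode(self, dna: str) -> tuple[Optional[bytes], DecodeStatus]:
        try:
            return transcode_rot3_inverse(dna), DecodeStatus.SUCCESS
        except ValueError:
            return None, DecodeStatus.DETECTED_FAILURE


# ---------------------------------------------------------------------------
# functional sites


@dataclass(frozen=True)
class FunctionalSites:
    prefix: str = ""
    suffix: str = ""

    def __post_init__(self) -> None:
        validate_dna(self.prefix)
        validate_dna(self.suffix)


def add_sites(dna: str, sites: FunctionalSites) -> str:
    return sites.prefix + dna + sites.suffix


def _strip_prefix(dna: str, prefix: str, tolerance: int) -> Optional[str]:
    if not prefix:
        return dna
    if dna.startswith(prefix):
        return dna[len(prefix):]
    # end-anchored approximate match: align the primer to a prefix of the read
    res = edlib.align(prefix, dna, mode="SHW", task="locations", k=tolerance)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    # among equally-scoring matches, cut at the end closest to the nominal
    # prefix length so indel-free substitutions strip exactly
    nominal = len(prefix) - 1
    end = min(
        (loc[1] for loc in res["locations"] if loc[1] is not None),
        key=lambda e: (abs(e - nominal), -e),
    )
    return dna[end + 1:]


def strip_sites(
    dna: str, sites: FunctionalSites, tolerance: int = 2
) -> tuple[Optional[str], DecodeStatus]:
    """Remove prefix/suffix sites, allowing up to ``tolerance`` edits each."""
    out = _strip_prefix(dna, sites.prefix, tolerance)
    if out is None:
        return None, DecodeStatus.DETECTED_FAILURE
    if sites.suffix:
        rev = _strip_prefix(out[::-1], sites.suffix[::-1], tolerance)
        if rev is None:
            return None, DecodeStatus.DETECTED_FAILURE
        out = rev[::-1]
    return out, DecodeStatus.SUCCESS


class SiteAdder(SiteStage):
    name = "functional_sites"

    def __init__(self, sites: FunctionalSites, tolerance: int = 2) -> None:
        self.sites = sites
        self.tolerance = tolerance

    def encode(self, dna: str) -> str:
        return add_sites(dna, self.sites)

    def decode(self, dna: str) -> tuple[Optional[str], DecodeStatus]:
        return strip_sites(dna, self.sites, self.tolerance)


# ---------------------------------------------------------------------------
# outer code (cross-strand Reed-Solomon)


def outer_rs_encode(packet: Packet, n_parity_strands: int) -> Packet:
    """Fill ``packet.parity_sequences`` with column-wise RS parity strands."""
    k = len(packet.data_sequences)
    if n_parity_strands < 0:
        raise ValueError("n_parity_strands must be >= 0")
    if k + n_parity_strands > 255:
        raise ValueError("k + c exceeds 255 strands per packet (GF(2^8) limit)")
    if n_parity_strands == 0 or k == 0:
        packet.parity_sequences = []
        return packet
    lengths = {len(s.payload) for s in packet.data_sequences}
    if len(lengths) != 1:
        raise ValueError("all payloads in a packet must have equal length")
    (paylen,) = lengths
    cfg = RSConfig(n_parity_strands, k)
    parity_cols = []
    for j in range(paylen):
        col = bytes(s.payload[j] for s in packet.data_sequences)
        parity_cols.append(rs_encode(col, cfg)[k:])
    packet.parity_sequences = [
        BaseSequence(
            payload=bytes(parity_cols[j][i] for j in range(paylen)),
            packet_id=packet.packet_id,
            position_in_packet=k + i,
            is_parity=True,
        )
        for i in range(n_parity_strands)
    ]
    return packet


def outer_rs_decode(
    rows: Sequence[Optional[bytes]],
    n_parity_strands: int,
    payload_len: int,
) -> tuple[list[bytes], DecodeStatus]:
    """Column-wise RS decode of one packet.

    ``rows`` holds one entry per strand slot (data strands first, then parity
    strands); ``None`` marks an erased strand. Returns the ``k`` recovered
    data payloads; on unrecoverable columns the received bytes are passed
    through and the status flags the failure.
    """
    n = len(rows)
    k = n - n_parity_strands
    if k < 1:
        raise ValueError("packet must contain at least one data strand")
    cfg = RSConfig(n_parity_strands, k)
    erasures = [i for i, r in enumerate(rows) if r is None]
    filled = [r if r is not None else bytes(payload_len) for r in rows]
    if any(len(r) != payload_len for r in filled):
        raise ValueError("row length mismatch")
    out_cols: list[bytes] = []
    status = DecodeStatus.SUCCESS
    for j in range(payload_len):
        col = bytes(r[j] for r in filled)
        if n_parity_strands == 0:
            out_cols.append(col[:k])
            continue
        res = rs_decode(col, cfg, erasures)
        if res.status is DecodeStatus.SUCCESS:
            out_cols.append(res.data)
        else:
            status = DecodeStatus.DETECTED_FAILURE
            out_cols.append(col[:k])
    data_rows = [
        bytes(out_cols[j][i] for j in range(payload_len)) for i in range(k)
    ]
    return data_rows, status
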