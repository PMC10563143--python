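"""Hash-convolutional DNA codec with beam-search decoding.

The encoder consumes the payload bit stream a few bits at a time and emits
one base per step:

    base_t = (H(t, context_t, salt) + v_t) mod 4

where ``v_t`` is the integer value of the bits consumed at step ``t``,
``context_t`` is the trailing window of previously consumed bits, and ``H``
is a splitmix64-based hash. Because the hash chains every emitted base to
the entire bit prefix, a single base error desynchronizes all later bases —
which is exactly what makes sequential decoding work: hypotheses with wrong
bits look random against the received strand and accumulate penalty quickly.

The decoder is a beam search over hypotheses ``(bit prefix, position in the
received strand)`` scoring substitutions, insertions and deletions with
configurable penalties, so it can re-synchronize across indels.

The code rate is expressed as a fraction of the 2 bits/base maximum
(rate 0.5 = 1 bit/base). Bits per step follow the Bresenham-like pattern
``n_t = floor((t+1)·2r) − floor(t·2r)``, which realizes any rational rate
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import ceil
from typing import Optional, Union

import numpy as np

from .codecs import TranscodeStage
from .rs import DecodeStatus
from .types import _BASE_TO_INT

_U64 = np.uint64
_C1 = _U64(0x9E3779B97F4A7C15)
_C2 = _U64(0xC2B2AE3D27D4EB4F)
_C3 = _U64(0x165667B19E3779F9)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    z = x + _C1
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


_M64 = (1 << 64) - 1


def _hash_base(pos: int, ctx: np.ndarray, salt: int) -> np.ndarray:
    """Low 2 bits of the position/context/salt hash, vectorized over ctx."""
    const = _U64(((pos * 0xC2B2AE3D27D4EB4F) ^ ((salt & _M64) * 0x9E3779B97F4A7C15)) & _M64)
    x = const ^ (ctx * _C3)
    return (_splitmix64(x) & _U64(3)).astype(np.int64)


@dataclass(frozen=True)
class HedgesConfig:
    """Parameters of the hash-convolutional codec.

    rate
        Fraction of the 2 bits/base maximum actually carried (0 < rate <= 1);
        floats are snapped to the nearest small rational (denominator <= 64),
        so the Table-style rates 0.167, 0.25, 0.5, 0.75 become 1/6, 1/4, 1/2,
        3/4 exactly.
    context_bits
        Length of the consumed-bit history hashed into each base.
    beam_width
        Number of hypotheses kept per decoding step.
    penalties
        (substitution, insertion, deletion) scores; a perfect match costs 0.
    """

    rate: Union[Fraction, float, str] = Fraction(1, 2)
    context_bits: int = 8
    beam_width: int = 32
    penalties: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fail_threshold_frac: float = 0.15  # of strand length, in deletion penalties
    flush_bases: int = 8  # zero-bit runout bases protecting the trailing bits

    def __post_init__(self) -> None:
        r = self.rate
        if not isinstance(r, Fraction):
            r = Fraction(str(r)).limit_denominator(64)
            object.__setattr__(self, "rate", r)
        if not (0 < r <= 1):
            raise ValueError("rate must be in (0, 1]")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if any(p < 0 for p in self.penalties):
            raise ValueError("penalties must be non-negative")
        if not (0 < self.context_bits <= 32):
            raise ValueError("context_bits must be in [1, 32]")

    def bits_pattern(self, n_bases: int) -> list[int]:
        two_r = 2 * self.rate
        return [
            int((t + 1) * two_r.numerator // two_r.denominator)
            - int(t * two_r.numerator // two_r.denominator)
            for t in range(n_bases)
        ]

    def n_bases(self, n_bits: int) -> int:
        """Payload bases only, excluding the flush runout."""
        two_r = 2 * self.rate
        return ceil(n_bits * two_r.denominator / two_r.numerator)

    def strand_length(self, n_bits: int) -> int:
        return self.n_bases(n_bits) + self.flush_bases


def hedges_encode(data: bytes, cfg: HedgesConfig, strand_salt: int = 0) -> str:
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
    n_bits = len(bits)
    if n_bits == 0:
        return ""
    total = cfg.n_bases(n_bits)
    pattern = cfg.bits_pattern(total) + [0] * cfg.flush_bases
    padded = np.zeros(sum(pattern), dtype=np.uint8)
    padded[:n_bits] = bits
    mask = _U64((1 << cfg.context_bits) - 1)
    ctx = _U64(0)
    out = []
    pos_bit = 0
    for t, n_t in enumerate(pattern):
        v = 0
        for b in padded[pos_bit : pos_bit + n_t]:
            v = (v << 1) | int(b)
        pos_bit += n_t
        h = int(_hash_base(t, np.array([ctx], dtype=_U64), strand_salt)[0])
        out.append("ACGT"[(h + v) & 3])
        ctx = ((ctx << _U64(n_t)) | _U64(v)) & mask
    return "".join(out)


@dataclass
class HedgesDecodeResult:
    status: DecodeStatus
    data: Optional[bytes] = None
    score: float = 0.0


def hedges_decode(
    dna: str,
    cfg: HedgesConfig,
    strand_salt: int = 0,
    expected_bits: int = 0,
) -> HedgesDecodeResult:
    """Beam-search decode of ``expected_bits`` payload bits from ``dna``.

    Hypotheses are (context, received-strand offset) pairs; each trellis step
    emits one base and may consume 0 (deletion), 1 (match/substitution) or
    2-3 (insertions then match) received bases. The best full-length
    hypothesis is returned unless its score exceeds the failure threshold.
    """
    if expected_bits <= 0:
        raise ValueError("expected_bits must be positive")
    if expected_bits % 8 != 0:
        raise ValueError("expected_bits must be a whole number of bytes")
    p_sub, p_ins, p_del = cfg.penalties
    recv = np.array([_BASE_TO_INT[c] for c in dna], dtype=np.int64)
    R = len(recv)
    total = cfg.n_bases(expected_bits)
    pattern = cfg.bits_pattern(total) + [0] * cfg.flush_bases
    mask = _U64((1 << cfg.context_bits) - 1)
    big = np.inf
    threshold = cfg.penalties[2] * ceil(cfg.fail_threshold_frac * max(R, 1))

    # beam state arrays
    ctx = np.zeros(1, dtype=_U64)
    idx = np.zeros(1, dtype=np.int64)
    score = np.zeros(1, dtype=np.float64)
    edits = np.zeros(1, dtype=np.int64)
    trace: list[tuple[np.ndarray, np.ndarray]] = []  # (parent, v) per step

    for t, n_t in enumerate(pattern):
        K = len(ctx)
        V = 1 << n_t
        # layout: parent-major, then guess, then transition type (0=del,
        # 1=match, 2=ins+match, 3=2ins+match) — parent-major ordering makes
        # the stable tie-break follow the bit-prefix order of the beam.
        n_trans = 4
        C = K * V * n_trans
        parent = np.repeat(np.arange(K, dtype=np.int64), V * n_trans)
        vv = np.tile(np.repeat(np.arange(V, dtype=np.int64), n_trans), K)
        tr = np.tile(np.arange(n_trans, dtype=np.int64), K * V)

        h = _hash_base(t, ctx, strand_salt)  # (K,)
        expected = (h[parent] + vv) & 3
        pidx = idx[parent]
        pscore = score[parent]
        pedits = edits[parent]

        n_ins = np.where(tr == 0, 0, tr - 1)  # insertions before the match
        consumed = np.where(tr == 0, 0, n_ins + 1)
        match_pos = pidx + n_ins
        valid = (tr == 0) | (match_pos < R)
        mp_safe = np.minimum(match_pos, R - 1) if R > 0 else np.zeros_like(match_pos)
        if R > 0:
            is_sub = recv[mp_safe] != expected
        else:
            is_sub = np.ones(C, dtype=bool)
        step_cost = np.where(
            tr == 0,
            p_del,
            n_ins * p_ins + np.where(is_sub, p_sub, 0.0),
        )
        step_edits = np.where(
            tr == 0, 1, n_ins + np.where(is_sub, 1, 0)
        )
        new_score = np.where(valid, pscore + step_cost, big)
        new_edits = pedits + step_edits
        new_idx = pidx + consumed
        new_ctx = ((ctx[parent] << _U64(n_t)) | vv.astype(_U64)) & mask

        # hypotheses already past the failure threshold can never win
        ok = np.isfinite(new_score) & (new_score <= threshold)
        parent, vv = parent[ok], vv[ok]
        new_score, new_edits = new_score[ok], new_edits[ok]
        new_idx, new_ctx = new_idx[ok], new_ctx[ok]
        if len(new_score) == 0:
            return HedgesDecodeResult(DecodeStatus.DETECTED_FAILURE)

        # dedupe identical (ctx, idx) states keeping the best-scoring one;
        # stable ordering makes ties deterministic
        key = new_ctx.astype(np.int64) * np.int64(R + 4) + new_idx
        order = np.lexsort((np.arange(len(key)), new_edits, new_score, key))
        key_sorted = key[order]
        first = np.ones(len(key_sorted), dtype=bool)
        first[1:] = key_sorted[1:] != key_sorted[:-1]
        keep = order[first]
        keep = keep[
            np.lexsort((keep, new_edits[keep], new_score[keep]))[: cfg.beam_width]
        ]

        trace.append((parent[keep], vv[keep]))
        ctx, idx = new_ctx[keep], new_idx[keep]
        score, edits = new_score[keep], new_edits[keep]

    # leftover received bases are trailing insertions
    score = score + (R - idx) * p_ins
    edits = edits + (R - idx)
    best = int(np.lexsort((np.arange(len(score)), edits, score))[0])
    best_score = float(score[best])
    if best_score > threshold:
        return HedgesDecodeResult(DecodeStatus.DETECTED_FAILURE, score=best_score)

    # traceback
    vs: list[int] = []
    b = best
    for t in range(len(pattern) - 1, -1, -1):
        par, vv = trace[t]
        vs.append(int(vv[b]))
        b = int(par[b])
    vs.reverse()
    bits = np.zeros(sum(pattern), dtype=np.uint8)
    pos = 0
    for n_t, v in zip(pattern, vs):
        for k in range(n_t):
            bits[pos + k] = (v >> (n_t - 1 - k)) & 1
        pos += n_t
    data = np.packbits(bits[:expected_bits]).tobytes()
    return HedgesDecodeResult(DecodeStatus.SUCCESS, data=data, score=best_score)


class HedgesTranscoder(TranscodeStage):
    """Transcoding stage adapter: serialized index+payload bytes <-> DNA.

    ``expected_bytes`` (index width + payload bytes, plus any binary-stage
    expansion) fixes the bit budget the decoder searches for. The salt is a
    per-pipeline constant: it must not depend on the strand index, because
    the index is only known *after* decoding.
    """

    name = "hedges"

    def __init__(
        self, cfg: HedgesConfig, expected_bytes: int, salt: int = 0
    ) -> None:
        self.cfg = cfg
        self.expected_bytes = expected_bytes
        self.salt = salt

    def encode(self, data: bytes) -> str:
        if len(data) != self.expected_bytes:
            raise ValueError(
                f"expected {self.expected_bytes} bytes, got {len(data)}"
            )
        return hedges_encode(data, self.cfg, self.salt)

    def decode(self, dna: str) -> tuple[Optional[bytes], DecodeStatus]:
        res = hedges_decode(
            dna, self.cfg, self.salt, expected_bits=8 * self.expected_bytes
        )
        return res.data, res.status
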