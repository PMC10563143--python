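"""Systematic Reed-Solomon code over GF(2^8) with errors-and-erasures decoding.

The codec is the workhorse of both the per-strand ("inner") byte protection
and the cross-strand ("outer") protection: a codeword of ``n_data`` message
bytes plus ``n_parity`` parity bytes can correct any combination of ``e``
errors and ``f`` erasures with ``2e + f <= n_parity``.

Generator roots are alpha^0 .. alpha^(n_parity-1) (first consecutive root
alpha^0), primitive polynomial 0x11D; parity is appended after the message so
codewords are systematic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterable, Optional

from .gf256 import EXP, gf_div, gf_mul, gf_pow


class DecodeStatus(Enum):
    SUCCESS = "success"
    DETECTED_FAILURE = "detected_failure"
    SILENT_CORRUPTION = "silent_corruption"


@dataclass(frozen=True)
class RSConfig:
    """``n_parity`` redundant bytes protecting ``n_data`` message bytes."""

    n_parity: int
    n_data: int

    def __post_init__(self) -> None:
        if self.n_parity < 0:
            raise ValueError("n_parity must be >= 0")
        if self.n_data < 1:
            raise ValueError("n_data must be >= 1")
        if self.n_data + self.n_parity > 255:
            raise ValueError("codeword length exceeds 255 (GF(2^8) limit)")

    @property
    def n_total(self) -> int:
        return self.n_data + self.n_parity


@dataclass
class RSDecodeResult:
    status: DecodeStatus
    data: Optional[bytes]  # message bytes when status is SUCCESS


@lru_cache(maxsize=64)
def _generator_poly(n_parity: int) -> tuple[int, ...]:
    # highest-degree-first; roots alpha^0 .. alpha^(n_parity-1)
    g = [1]
    for i in range(n_parity):
        root = gf_pow(2, i)
        nxt = [0] * (len(g) + 1)
        for j, c in enumerate(g):
            nxt[j] ^= gf_mul(c, 1)
            nxt[j + 1] ^= gf_mul(c, root)
        g = nxt
    return tuple(g)


def rs_encode(data: bytes, cfg: RSConfig) -> bytes:
    if len(data) != cfg.n_data:
        raise ValueError(f"expected {cfg.n_data} data bytes, got {len(data)}")
    if cfg.n_parity == 0:
        return bytes(data)
    gen = _generator_poly(cfg.n_parity)
    rem = list(data) + [0] * cfg.n_parity
    for i in range(cfg.n_data):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= gf_mul(gen[j], coef)
    return bytes(data) + bytes(rem[cfg.n_data:])


def _syndromes(codeword: Iterable[int], n_parity: int) -> list[int]:
    cw = list(codeword)
    out = []
    for i in range(n_parity):
        x = gf_pow(2, i)
        y = 0
        for c in cw:
            y = gf_mul(y, x) ^ c
        out.append(y)
    return out


def _poly_mul_le(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi == 0:
            continue
        for j, qj in enumerate(q):
            if qj:
                out[i + j] ^= gf_mul(pi, qj)
    return out


def _poly_eval_le(p: list[int], x: int) -> int:
    y = 0
    for c in reversed(p):
        y = gf_mul(y, x) ^ c
    return y


def _berlekamp_massey(synd: list[int]) -> tuple[list[int], int]:
    """Return (error locator, L) from (Forney) syndromes, little-endian."""
    C = [1]
    B = [1]
    L = 0
    m = 1
    b = 1
    for n in range(len(synd)):
        d = synd[n]
        for i in range(1, L + 1):
            if i < len(C):
                d ^= gf_mul(C[i], synd[n - i])
        if d == 0:
            m += 1
            continue
        coef = gf_div(d, b)
        shifted = [0] * m + [gf_mul(coef, c) for c in B]
        newC = [0] * max(len(C), len(shifted))
        for i, c in enumerate(C):
            newC[i] ^= c
        for i, c in enumerate(shifted):
            newC[i] ^= c
        if 2 * L <= n:
            B = C
            b = d
            L = n + 1 - L
            m = 1
        else:
            m += 1
        C = newC
    while len(C) > 1 and C[-1] == 0:
        C.pop()
    return C, L


def rs_decode(
    codeword: bytes,
    cfg: RSConfig,
    erasure_positions: Iterable[int] = (),
) -> RSDecodeResult:
    """Errors-and-erasures decode of a systematic codeword.

    ``erasure_positions`` are byte indices into the codeword whose values are
    known to be unreliable (e.g. dropped strands in the outer code). Returns
    ``DETECTED_FAILURE`` when the errata exceed capability and the syndrome
    check notices; miscorrections beyond capability surface as apparent
    success and are classified upstream against ground truth.
    """
    n = cfg.n_total
    if len(codeword) != n:
        raise ValueError(f"expected {n} codeword bytes, got {len(codeword)}")
    erasures = sorted(set(int(p) for p in erasure_positions))
    if any(p < 0 or p >= n for p in erasures):
        raise ValueError("erasure position out of range")
    if cfg.n_parity == 0:
        return RSDecodeResult(DecodeStatus.SUCCESS, bytes(codeword[: cfg.n_data]))
    if len(erasures) > cfg.n_parity:
        return RSDecodeResult(DecodeStatus.DETECTED_FAILURE, None)

    cw = list(codeword)
    synd = _syndromes(cw, cfg.n_parity)
    if not any(synd) and not erasures:
        return RSDecodeResult(DecodeStatus.SUCCESS, bytes(cw[: cfg.n_data]))

    # erasure locator Gamma(x) = prod (1 + X_j x), X_j = alpha^(n-1-j)
    gamma = [1]
    for p in erasures:
        gamma = _poly_mul_le(gamma, [1, gf_pow(2, n - 1 - p)])

    # Forney syndromes T(x) = S(x) * Gamma(x) mod x^n_parity; only the
    # entries past the first f follow the error-locator LFSR recursion.
    t = _poly_mul_le(synd, gamma)[: cfg.n_parity]
    lam, n_err = _berlekamp_massey(t[len(erasures):])
    if 2 * n_err + len(erasures) > cfg.n_parity:
        return RSDecodeResult(DecodeStatus.DETECTED_FAILURE, None)

    psi = _poly_mul_le(gamma, lam)
    while len(psi) > 1 and psi[-1] == 0:
        psi.pop()
    deg_psi = len(psi) - 1

    # Chien search over codeword positions
    positions = []
    for j in range(n):
        x_inv = EXP[(255 - ((n - 1 - j) % 255)) % 255]
        if _poly_eval_le(psi, x_inv) == 0:
            positions.append(j)
    if len(positions) != deg_psi:
        return RSDecodeResult(DecodeStatus.DETECTED_FAILURE, None)

    # error evaluator Omega(x) = S(x) Psi(x) mod x^n_parity
    omega = _poly_mul_le(synd, psi)[: cfg.n_parity]
    # formal derivative of Psi: odd-power coefficients shift down by one
    psi_prime = [psi[i] for i in range(1, len(psi), 2)]
    psi_prime_full = [0] * (len(psi) - 1)
    for k, c in enumerate(psi_prime):
        psi_prime_full[2 * k] = c

    for j in positions:
        x = gf_pow(2, n - 1 - j)
        x_inv = gf_div(1, x)
        denom = _poly_eval_le(psi_prime_full, x_inv)
        if denom == 0:
            return RSDecodeResult(DecodeStatus.DETECTED_FAILURE, None)
        mag = gf_mul(x, gf_div(_poly_eval_le(omega, x_inv), denom))
        cw[j] ^= mag

    if any(_syndromes(cw, cfg.n_parity)):
        return RSDecodeResult(DecodeStatus.DETECTED_FAILURE, None)
    return RSDecodeResult(DecodeStatus.SUCCESS, bytes(cw[: cfg.n_data]))
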