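"""Arithmetic over GF(2^8) with primitive polynomial 0x11D.

Log/antilog tables are built once at import; all byte-level Reed-Solomon
operations in :mod:`strandsim.rs` are defined on top of these primitives so
that parity bytes are bit-exact across platforms.
"""

from __future__ import annotations

PRIMITIVE_POLY = 0x11D  # x^8 + x^4 + x^3 + x^2 + 1

EXP = [0] * 512  # antilog table, doubled to avoid mod-255 in hot paths
LOG = [0] * 256

_x = 1
for _i in range(255):
    EXP[_i] = _x
    LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= PRIMITIVE_POLY
for _i in range(255, 512):
    EXP[_i] = EXP[_i - 255]


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return EXP[LOG[a] + LOG[b]]


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(2^8)")
    if a == 0:
        return 0
    return EXP[(LOG[a] - LOG[b]) % 255]


def gf_pow(a: int, n: int) -> int:
    if a == 0:
        return 0 if n > 0 else 1
    return EXP[(LOG[a] * n) % 255]


def gf_inv(a: int) -> int:
    return gf_div(1, a)


def poly_mul(p: list[int], q: list[int]) -> list[int]:
    """Multiply polynomials with coefficients in GF(2^8), highest degree first."""
    out = [0] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi == 0:
            continue
        for j, qj in enumerate(q):
            if qj:
                out[i + j] ^= gf_mul(pi, qj)
    return out


def poly_eval(p: list[int], x: int) -> int:
    """Horner evaluation; p is highest degree first."""
    y = 0
    for c in p:
        y = gf_mul(y, x) ^ c
    return y


def poly_scale(p: list[int], s: int) -> list[int]:
    return [gf_mul(c, s) for c in p]


def poly_add(p: list[int], q: list[int]) -> list[int]:
    out = [0] * max(len(p), len(q))
    out[len(out) - len(p):] = p
    for i, c in enumerate(q):
        out[len(out) - len(q) + i] ^= c
    return out
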