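"""Deterministic seed derivation.

Every source of randomness in a campaign is seeded from a single master seed
by hashing the coordinates of the work unit (run index, iteration, strand,
copy). Hashing rather than sequential draws means the result never depends
on execution order, which is what makes worker-count-independent replay
possible.
"""

from __future__ import annotations

import hashlib


def derive_seed(*parts: int) -> int:
    """Hash integer coordinates into a 63-bit child seed."""
    h = hashlib.blake2b(digest_size=8)
    for p in parts:
        h.update(int(p).to_bytes(16, "big", signed=True))
    return int.from_bytes(h.digest(), "big") >> 1
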