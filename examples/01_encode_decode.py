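"""Encode a byte block into a DNA strand library and decode it back.

The pipeline whitens the data, protects each strand's index+payload with a
(9,47) Reed-Solomon code over GF(2^8), and transcodes at 2 bits/base: every
strand is (4+47+9) bytes x 4 bases/byte = 240 bases. Two strands are then
deleted to show whole-strand erasure recovery by the outer code.
"""

import numpy as np

from strandsim import decode, encode, rs_pipeline

rng = np.random.default_rng(0)
data = rng.integers(0, 256, size=1000, dtype=np.uint8).tobytes()

spec = rs_pipeline(9, 47, strands_per_packet=20, outer_parity_strands=4)
strands = encode(spec, data)
print(f"{len(data)} bytes -> {len(strands)} strands "
      f"({sum(s.is_parity for s in strands)} outer parity), "
      f"{len(strands[0].dna)} bases each")

# drop two whole strands: the outer code treats them as erasures
surviving = [s for s in strands if s.origin_index not in (3, 17)]
out, stats = decode(
    spec,
    [s.dna for s in surviving],
    expected_total=len(strands),
    origins=[s.origin_index for s in surviving],
    original_length=len(data),
)
print(f"dropped strands 3 and 17; recovered file intact: {out == data}")
print(f"erasures seen by the outer code: {stats.counters['consolidation_erasures']}")
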