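# strandsim

Fault-injection simulation and cost analysis for DNA-based data storage
pipelines.

DNA data storage systems encode binary files into libraries of short
synthetic DNA strands and read them back through noisy sequencing. Designs
differ in how they spend redundancy: per-strand ("inner") error-correcting
codes, cross-strand ("outer") codes against whole-strand loss, and
sequencing depth consolidated by alignment and voting. Because synthesis and
sequencing cost scale with the number of bases, competing designs are
compared by **write density** and **read density** — user data bits per base
synthesized / sequenced. `strandsim` is a test bed for making that
comparison *in silico*: it encodes data through a modular staged pipeline,
injects channel errors, decodes, measures per-strand decode rates, and turns
them into provisioned density numbers a designer can act on.

## What is in the box

- **Staged pipeline model** — files are split into *packets* (the outer-code
  scope) of strand-sized *base-sequences*; each gets an incremental
  big-endian index, then runs through binary transformations, a single
  binary-to-DNA transcoding stage, and functional-site affixes (e.g. PCR
  primers). Composition is validated (one transcoder; binary stages before
  it, sites after).
- **Codecs** — a whitening randomizer (xorshift64\*), systematic
  Reed-Solomon over GF(2^8) (primitive polynomial 0x11D) used both
  per-strand and column-wise across strands with errors-and-erasures
  decoding (`2e + f <= n_parity`), dense 2 bits/base and homopolymer-free
  base-3 rotation transcoders, and a hash-convolutional DNA codec
  (splitmix64 position/context/salt hash) decoded by beam search that
  re-synchronizes across insertions and deletions.
- **Channel** — constant or Poisson sequencing depth with dropout, i.i.d.
  substitution/insertion/deletion injection, and a k-mer-conditional model
  with geometric deletion bursts (nanopore-like). Every injection returns a
  replayable edit log.
- **Consolidation** — ideal (truth-tagged) clustering with star-MSA
  consensus (medoid pivot, per-column plurality vote) before inner
  decoding, and/or byte-wise majority voting after it.
- **Campaign driver** — JSON configs where any list-valued parameter sweeps
  a cross-product of runs, each with a hash-derived seed and a parameter-
  named output directory; statistics are mergeable counters, so results are
  byte-identical for any worker count.
- **Analysis** — Wilson-interval decode rates, exact trinomial packet
  failure probability `P[2S + E > c]`, minimal outer parity `c` meeting a
  mean-time-to-failure target, densities, and Pareto-front extraction.

## A worked example

```python
import numpy as np
from strandsim import rs_pipeline, encode, decode

data = np.random.default_rng(0).integers(0, 256, 1000, dtype=np.uint8).tobytes()
spec = rs_pipeline(9, 47, strands_per_packet=20, outer_parity_strands=4)
strands = encode(spec, data)
# -> 30 strands (8 outer parity), each (4+47+9) bytes * 4 bases/byte = 240 bases

surviving = [s for s in strands if s.origin_index not in (3, 17)]
out, stats = decode(spec, [s.dna for s in surviving], len(strands),
                    origins=[s.origin_index for s in surviving],
                    original_length=len(data))
assert out == data   # two dropped strands recovered as outer-code erasures
```

Running `python examples/01_encode_decode.py` prints:

```
1000 bytes -> 30 strands (8 outer parity), 240 bases each
dropped strands 3 and 17; recovered file intact: True
erasures seen by the outer code: 2
```

The other examples walk through fault-injection sweeps with decode-rate
confidence intervals (`02`), the gain of star-MSA consensus over individual
noisy copies (`03`), read-to-strand mapping by index or by alignment (`04`),
and the full density case study with Pareto fronts (`05`). A thin CLI wraps
the same functions: `strandsim simulate|encode|decode|map-reads|analyze`.

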