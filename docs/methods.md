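# Methods

This note records the models implemented by `strandsim`, the conventions
chosen where the problem is genuinely open, and what the bundled synthetic
experiments do and do not demonstrate.

## Information model

A file is encoded in two nested scopes.

**Across strands.** The byte stream is cut into *packets*, each packet into
equal-length *base-sequences* (the last one zero-padded; the original length
travels out-of-band in the run manifest so padding never perturbs density
arithmetic). The outer code operates within one packet: a column-wise
Reed-Solomon code over GF(2^8) in which byte *j* of every strand forms one
codeword, so a missing strand is an erasure in every column and a silently
wrong strand is an error in every column. Every base-sequence — data first,
then parity — receives a consecutive integer index, serialized big-endian in
a fixed width (default 4 bytes) and prepended to the payload. The index
hook is pluggable so seed-based (fountain-style) indexing can be added; only
incremental indexing is implemented.

**Within a strand.** The serialized index+payload passes through an ordered
cascade: any number of *binary transformations* (whitening, inner RS),
exactly one *transcoding* stage mapping bytes to DNA, then any number of
*functional site* affixes (primer-like strings). Validation enforces this
order and reports violations as data, not exceptions. The index is
deliberately inside the inner code's protection: with a 4-byte index and an
(x, y) = (parity, payload) inner RS configuration with x + y + 4 = 60, the
2 bits/base transcoder yields exactly 240-base strands for all four bundled
configurations — the strand-length regime practical synthesis supports.

## Codecs

**Reed-Solomon.** Systematic, primitive polynomial 0x11D, generator roots
α^0…α^(n_parity−1); decoding uses Forney syndromes with an erasure locator,
Berlekamp-Massey on the post-erasure syndrome tail, Chien search and the
Forney algorithm, then a final syndrome re-check. Any combination of e
errors and f erasures with 2e + f ≤ n_parity is corrected; the capability
boundary is enforced by exhaustive small-case tests rather than assumed.

**Hash-convolutional codec.** Each emitted base is
`(H(position, context, salt) + v) mod 4`, where `v` is the integer of the
bits consumed at that step, the context is the trailing window of consumed
bits (default 8), and `H` is a splitmix64-based hash. The code rate is a
fraction of the 2 bits/base maximum, realized exactly for any rational by a
Bresenham bit-allocation pattern (e.g. rate 3/4 → bases carrying 2,1,2,1,…
bits). After the payload, a configurable run of *flush bases* (default 8)
that consume zero bits is appended: they chain the final context into
observable bases, without which errors in the last few positions could be
reinterpreted as different trailing payload bits at equal or better score.
Strand length is therefore `ceil(bits / (2·rate)) + flush`. Decoding is a
beam search over (bit-prefix, received-position) hypotheses with
substitution/insertion/deletion penalties (default 1 each), per-step
deduplication of identical (context, position) states, a deterministic
tie-break (score, then edit count, then a fixed enumeration order that
follows the bit-prefix ordering of the beam), and a failure threshold of
`deletion_penalty × ceil(0.15 × strand_length)` — hypotheses past the
threshold are pruned, so hopeless strands fail fast. The decoder has no
integrity check of its own; undetected wrong decodes surface as silent
errors and are charged two parity strands by the outer code, which is why
voting over copies or an MSA front-end matters at higher error rates.

**Transcoders.** The 2-bit map is 00→A, 01→C, 10→G, 11→T, most-significant
bits first. The rotation transcoder writes the byte block as one big-endian
integer in base 3 (digit width fixed by the block length) and lets each
digit choose among the three bases differing from the previous one, so no
homopolymer of length 2 ever appears, at log2(3) ≈ 1.585 bits/base.

**Functional sites.** Affix stripping tries an exact match, then an
end-anchored alignment within an edit tolerance (default 2); among
equal-score matches the cut closest to the nominal site length is taken, so
substitution-only noise strips exactly.

## Channel

Copy counts are constant or Poisson with an optional whole-strand dropout
probability. Error injection scans the clean strand left to right: before
each position (and once past the end) a geometric number of uniform
insertions; the position itself is deleted with p_del, else substituted with
p_sub (uniform over the other three bases). This ordering convention is
pinned by an edit-log replay identity — replaying the log against the clean
strand must reproduce the noisy copy byte-for-byte — so an alternative
convention is a one-function change that the tests would localize.

The contextual model looks rates up by the preceding k clean bases with a
mandatory default row, draws substitution targets from a per-context
distribution (renormalized to exclude the original base), and extends any
triggered deletion geometrically with probability `burst_continue`
(mean burst `1/(1−q)`), emulating the burst-deletion structure of nanopore
channels. The bundled table is **synthetic** — homopolymer-biased deletions,
`burst_continue` 0.4 — and is a shape-compatible stand-in, not a fit to real
reads; measured k-mer tables can be loaded from TSV.

A named i.i.d. rate of x% means a *total* per-base event rate split equally,
x/3 each for substitution, insertion and deletion.

## Consolidation

Star MSA: the pivot is the medoid (minimum summed edit distance; ties to
the shorter, then lexicographically smaller member, making the result
independent of read order), every member is globally aligned to it with unit
costs, insertion runs are keyed by (pivot offset, run position), and each
column takes a plurality vote over {A,C,G,T,gap}. A gap wins only by strict
majority — a deliberate bias toward retaining bases that counters
deletion-heavy channels; base ties break alphabetically. The function is the
single extension point for an external multiple aligner. Post-decode voting
keeps only successfully decoded copies of an index and votes byte-wise
(ties to the lowest byte value). Clustering is *ideal* (reads carry their
ground-truth origin), isolating consensus behavior from clustering
approximations; a similarity-based clusterer is an explicit extension point.

## Campaign driver

All randomness derives from hashing (master seed, run, iteration, strand,
copy) with blake2b, never from sequential draws, so statistics are
byte-identical for any worker count and any execution order; this is
asserted by a 1-vs-8-worker test. Statistics are mergeable counters and
position histograms with canonical JSON serialization. Iteration failures
are recorded and retried once, never aborting a campaign. The three-level
work decomposition (runs → iterations → per-strand work) matches what an
MPI or batch-scheduler backend would use; the bundled implementation is a
local process pool.

## Provisioning and densities

Per-strand outcomes are classified against ground truth into success,
erasure (detected failure or missing index) and silent corruption. A packet
of k data + c parity strands fails when `2S + E > c`, with (S, E) the
silent/erasure counts modelled as a trinomial over k + c independent
strands; the probability is summed exactly (log-space binomials) and is
oracle-checked against scipy's multinomial. Provisioning picks the smallest
c for which the whole file (1 MB, i.e. 8×10^6 bits, by default) fails at
most once per 10^9 accesses, treating accesses as independent file reads.
Write density counts only user payload bits over all synthesized bases
(index, inner and outer parity are overhead); read density divides further
by sequencing depth. Physical dropout is excluded from provisioning by
default and can be folded into the erasure rate via a flag.

The default packet size for provisioning is k = 200 data strands. The
bundled case study provisions with k = 50: silent errors cost two parity
strands, and with k = 200 the GF(2^8) field limit caps parity at 55 strands
(≈27% overhead), which discards configurations with percent-level silent
rates as infeasible instead of pricing them; k = 50 leaves headroom so the
comparison surface stays populated.

## The bundled case study and its scale

`strandsim.casestudy.run_case_study` compares three designs — inner RS
behind MSA consensus, the convolutional codec decoding each copy
independently, and the convolutional codec on the MSA consensus — at total
i.i.d. error rates of 1% and 10%, depths {3, 9, 15} for the MSA pipelines
and depth 1 for the copy-independent one (each strand sequenced once, so
its read density equals its write density). Problem sizes are desk-scale by
design: a 120-byte input (5–10 strands per iteration) and 100 iterations
per run, giving 500–1000 strand samples per configuration — enough for the
qualitative front structure, not for tail-accurate rate estimates. The
full-scale campaign shape (2780-byte input, 1024 iterations, four inner
configurations per family, the {3,5,10,15,20,25,30} depth grid and four
error models, 240 runs in all) ships as
`examples/configs/case_study_full.json`; expanding it is tested, executing
it is a cluster-scale undertaking.

What the synthetic experiments show: the relative economics of spending
depth on consensus versus inner-code redundancy, and how the frontier
shifts with the channel error rate. What they do not show: absolute decode
rates of real chemistry (the error models are parametric, the nanopore
table synthetic), clustering cost (clustering is ideal), or PCR/synthesis
biases (not modelled).

## Known limitations

- Cascaded outer codes are interface-only (a second outer stage raises
  `NotImplementedError`); index handling across cascade levels is not
  defined here.
- The convolutional decoder's tie-break follows the beam's bit-prefix
  ordering only through its stable sort; it is deterministic, but not a
  total lexicographic order over all abandoned hypotheses.
- `edit_distance` with a band returns `band + 1` when the true distance
  exceeds the band (an "exceeded" marker, not the exact distance).
- Quality scores are placeholders in FASTQ output; quality-weighted voting
  is out of scope.
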