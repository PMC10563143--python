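"""Consolidation of multiple noisy copies of a strand.

Two strategies are provided, matching the two places a decoder can spend its
sequencing depth:

* **star-MSA consensus before inner decoding** — cluster the reads (ideal,
  truth-tagged clustering here), pick the medoid as pivot, globally align
  every member to it, and take a per-column plurality vote; the consensus is
  then inner-decoded once; and
* **majority voting after inner decoding** — inner-decode every copy
  independently, discard detected failures, and vote byte-wise over the
  surviving payloads.

The star alignment uses unit-cost global alignment (edlib) against the
medoid, so it is deterministic and needs no external aligner; an external
multiple-aligner can be slotted in by replacing :func:`msa_consensus` with
any function of the same signature.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .rs import DecodeStatus
from .types import DNA_ALPHABET, DecodeOutcome, IndexedSequence

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ReadCluster:
    members: list[str]
    truth_origin: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be nonempty")


def cluster_ideal(reads: Sequence[tuple[str, int]]) -> list[ReadCluster]:
    """Group reads by their ground-truth origin (fault-injection mode).

    Origins with zero surviving copies simply have no cluster and surface as
    erasures downstream. Output is sorted by origin, members keep read order.
    """
    by_origin: dict[int, list[str]] = {}
    for dna, origin in reads:
        by_origin.setdefault(origin, []).append(dna)
    return [
        ReadCluster(members=by_origin[o], truth_origin=o)
        for o in sorted(by_origin)
    ]


def edit_distance(a: str, b: str, band: Optional[int] = None) -> int:
    """Unit-cost Levenshtein distance.

    With ``band`` set, the search is limited to distances <= band (which is
    sufficient, and exact, whenever the true distance fits the band); if the
    true distance exceeds the band, ``band + 1`` is returned as an exceeded
    marker.
    """
    if band is not None and band < abs(len(a) - len(b)):
        raise ValueError("band must be >= |len(a) - len(b)|")
    res = edlib.align(a, b, mode="NW", k=-1 if band is None else band)
    d = res["editDistance"]
    if d < 0:
        return band + 1  # type: ignore[operator]
    return d


def _medoid(members: Sequence[str]) -> str:
    """Member minimizing summed edit distance; ties broken by shorter
    length then lexicographic order, making the choice permutation-invariant."""
    uniq = sorted(set(members), key=lambda s: (len(s), s))
    if len(uniq) == 1:
        return uniq[0]
    counts = Counter(members)
    best = None
    for cand in uniq:
        total = sum(edit_distance(cand, other) * counts[other] for other in uniq)
        key = (total, len(cand), cand)
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1]


def _align_to_pivot(member: str, pivot: str) -> list[tuple[str, int, int]]:
    """Yield (op, member_pos, pivot_pos) steps of the global alignment."""
    res = edlib.align(member, pivot, mode="NW", task="path")
    steps: list[tuple[str, int, int]] = []
    qi = pi = 0
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        for _ in range(int(count)):
            if op in "=XM":
                steps.append(("M", qi, pi))
                qi += 1
                pi += 1
            elif op == "I":  # member-only base: insertion relative to pivot
                steps.append(("I", qi, pi))
                qi += 1
            else:  # 'D': pivot base missing from member
                steps.append(("D", qi, pi))
                pi += 1
    return steps


GAP = "-"


def msa_consensus(cluster: ReadCluster) -> str:
    """Star-MSA consensus: medoid pivot, per-column plurality vote.

    Columns live in pivot coordinates; insertion runs are keyed by (number of
    pivot bases consumed, offset within the run) so that equal-placed
    insertions across members vote in the same column. A gap wins a column
    only by strict majority (biasing toward retaining bases, which counters
    deletion-heavy channels); ties among bases break alphabetically.
    """
    members = cluster.members
    if len(members) == 1:
        return members[0]
    pivot = _medoid(members)
    n = len(members)
    # column key: (pivot_pos, 0, offset) for insertions before pivot_pos,
    # (pivot_pos, 1, 0) for the pivot column itself
    votes: dict[tuple[int, int, int], Counter] = {}
    for member in members:
        run_pi: Optional[int] = None
        run_off = 0
        for op, qi, pi in _align_to_pivot(member, pivot):
            if op == "I":
                if run_pi != pi:
                    run_pi, run_off = pi, 0
                votes.setdefault((pi, 0, run_off), Counter())[member[qi]] += 1
                run_off += 1
            else:
                run_pi = None
                votes.setdefault((pi, 1, 0), Counter())[
                    member[qi] if op == "M" else GAP
                ] += 1
    out: list[str] = []
    for key in sorted(votes):
        counter = votes[key]
        base_votes = sum(v for b, v in counter.items() if b != GAP)
        gap_count = n - base_votes  # members absent from the column count as gaps
        if gap_count * 2 > n or base_votes == 0:
            continue
        top = max(counter.get(b, 0) for b in DNA_ALPHABET)
        out.append(next(b for b in DNA_ALPHABET if counter.get(b, 0) == top))
    return "".join(out)


def vote_decoded(outcomes: Sequence[DecodeOutcome]) -> DecodeOutcome:
    """Byte-wise plurality vote over successfully decoded copies of one index.

    Detected failures are discarded; with no survivors the index becomes an
    erasure. Payload length disagreements resolve to the modal length
    (ties -> shortest); byte ties resolve to the lowest byte value.
    """
    survivors = [
        o for o in outcomes
        if o.status is DecodeStatus.SUCCESS and o.recovered is not None
    ]
    if not survivors:
        return DecodeOutcome(status=DecodeStatus.DETECTED_FAILURE)
    lengths = Counter(len(o.recovered.payload) for o in survivors)
    target_len = min(
        (l for l, c in lengths.items() if c == max(lengths.values())),
    )
    pool = [o for o in survivors if len(o.recovered.payload) == target_len]
    voted = bytearray(target_len)
    for j in range(target_len):
        counts = Counter(o.recovered.payload[j] for o in pool)
        top = max(counts.values())
        voted[j] = min(b for b, c in counts.items() if c == top)
    first = pool[0].recovered
    return DecodeOutcome(
        status=DecodeStatus.SUCCESS,
        recovered=IndexedSequence(
            index=first.index,
            index_width=first.index_width,
            payload=bytes(voted),
            is_parity=first.is_parity,
        ),
    )
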