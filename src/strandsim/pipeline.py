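"""Staged information-flow model: packetization, indexing, stage ordering
validation, and the encode/decode drivers.

A file is encoded in two scopes. Across strands, it is broken into
*packets* — the scope of the outer error-correcting code — and each packet
into strand-sized *base-sequences*; the outer code adds parity
base-sequences, and every base-sequence receives a global incremental index.
Within a strand, the serialized index+payload runs through the single-strand
stage cascade (binary transformations, then the one transcoding stage, then
functional-site affixes) to become a DNA string.

Decoding reverses each stage. Multiple noisy copies per strand are reduced
either by star-MSA consensus before the inner stages are reversed, by
majority voting on decoded payloads afterwards, both, or neither; missing
indices then become erasures for the outer code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .codecs import (
    BinaryStage,
    SiteStage,
    Stage,
    StageCategory,
    TranscodeStage,
    outer_rs_decode,
    outer_rs_encode,
)
from .consensus import cluster_ideal, msa_consensus, vote_decoded
from .rs import DecodeStatus
from .stats import RunStats
from .types import (
    BaseSequence,
    DecodeOutcome,
    EncodedStrand,
    IndexedSequence,
    Packet,
)

CONSOLIDATION_MODES = ("pre_inner_msa", "post_inner_vote", "both", "none")
PROBE_POINTS = ("pre_inner", "post_binary", "post_transcode", "final")


class PipelineValidationError(ValueError):
    def __init__(self, violations: list[str]) -> None:
        super().__init__("; ".join(violations))
        self.violations = violations


class EmptyInputError(ValueError):
    pass


@dataclass
class OuterRSStage:
    """Cross-strand Reed-Solomon outer code: ``n_parity_strands`` parity
    base-sequences per packet."""

    n_parity_strands: int = 0


@dataclass
class Probe:
    """Transparent pipeline component: snapshots strand state at a stage
    boundary during encoding, for comparison during decoding. Never alters
    payload bytes or bases."""

    name: str
    point: str = "pre_inner"


@dataclass
class PipelineSpec:
    """An ordered, validated composition of stage components.

    ``payload_bytes`` is the user data per strand (the index is prepended on
    top of it before the inner stages run). ``outer_stages`` accepts a list
    for interface compatibility with cascaded outer codes, but exactly one
    level is implemented.
    """

    inner_stages: list[Stage]
    payload_bytes: int
    index_width: int = 4
    strands_per_packet: int = 200
    outer_stages: list[OuterRSStage] = field(default_factory=list)
    consolidation_mode: str = "none"
    probes: list[Probe] = field(default_factory=list)
    name: str = "pipeline"

    @property
    def outer_parity_strands(self) -> int:
        return self.outer_stages[0].n_parity_strands if self.outer_stages else 0

    @property
    def serialized_bytes(self) -> int:
        return self.index_width + self.payload_bytes


def validate_pipeline(spec: PipelineSpec) -> list[str]:
    """Return every ordering/category violation, in deterministic order.

    Violations are data, not exceptions; an empty list means the composition
    is logically arranged.
    """
    v: list[str] = []
    if spec.payload_bytes < 1:
        v.append("payload_bytes must be >= 1")
    if spec.index_width < 1:
        v.append("index_width must be >= 1")
    if not spec.inner_stages:
        v.append("no inner stages: a transcoding stage is required")
    transcoders = [
        s for s in spec.inner_stages if s.category is StageCategory.TRANSCODING
    ]
    if len(transcoders) > 1:
        v.append("multiple transcoders: binary-to-DNA transcoding can occur only once")
    elif spec.inner_stages and not transcoders:
        v.append("missing transcoder: no binary-to-DNA stage present")
    rank = {
        StageCategory.BINARY_TRANSFORMATION: 0,
        StageCategory.TRANSCODING: 1,
        StageCategory.FUNCTIONAL_SITE_ENCODING: 2,
    }
    last = -1
    for i, s in enumerate(spec.inner_stages):
        r = rank[s.category]
        if r < last:
            v.append(
                f"stage {i} ({s.name}): {s.category.value} cannot follow "
                f"a later-category stage"
            )
        last = max(last, r)
    if spec.consolidation_mode not in CONSOLIDATION_MODES:
        v.append(f"unknown consolidation_mode {spec.consolidation_mode!r}")
    if spec.outer_stages:
        c = spec.outer_stages[0].n_parity_strands
        if c < 0:
            v.append("outer parity strand count must be >= 0")
        if spec.strands_per_packet + c > 255:
            v.append("strands per packet + outer parity exceeds 255 (GF(2^8))")
    for p in spec.probes:
        if p.point not in PROBE_POINTS:
            v.append(f"probe {p.name!r}: unknown attachment point {p.point!r}")
    return v


# ---------------------------------------------------------------------------
# packetization and indexing


def partition_file(
    data: bytes, payload_bytes_per_strand: int, strands_per_packet: int
) -> list[Packet]:
    """Break a byte block into packets of strand-sized base-sequences.

    The final base-sequence is zero-padded to full length; the original
    length is carried out-of-band (run manifest), not in-band.
    """
    if payload_bytes_per_strand < 1 or strands_per_packet < 1:
        raise ValueError("payload size and strands per packet must be >= 1")
    if len(data) == 0:
        raise EmptyInputError("cannot partition an empty byte block")
    n_strands = math.ceil(len(data) / payload_bytes_per_strand)
    packets: list[Packet] = []
    for s in range(n_strands):
        pid, pos = divmod(s, strands_per_packet)
        if pid == len(packets):
            packets.append(Packet(packet_id=pid, data_sequences=[]))
        chunk = data[
            s * payload_bytes_per_strand : (s + 1) * payload_bytes_per_strand
        ]
        chunk = chunk.ljust(payload_bytes_per_strand, b"\x00")
        packets[pid].data_sequences.append(
            BaseSequence(payload=chunk, packet_id=pid, position_in_packet=pos)
        )
    return packets


def assign_indices(
    packets: Sequence[Packet], index_width: int
) -> list[IndexedSequence]:
    """Consecutive big-endian indices starting at 0 over the global strand
    order: all data base-sequences in packet/position order first, then all
    parity base-sequences."""
    ordered: list[BaseSequence] = []
    for p in packets:
        ordered.extend(p.data_sequences)
    for p in packets:
        ordered.extend(p.parity_sequences)
    if len(ordered) > 256**index_width:
        raise ValueError(
            f"{len(ordered)} strands overflow a {index_width}-byte index"
        )
    return [
        IndexedSequence(
            index=i,
            index_width=index_width,
            payload=seq.payload,
            is_parity=seq.is_parity,
        )
        for i, seq in enumerate(ordered)
    ]


def infer_erasures(recovered: set[int], expected_total: int) -> set[int]:
    """Missing strand indices, to be declared as erasures to the outer code."""
    bad = {i for i in recovered if i < 0 or i >= expected_total}
    if bad:
        raise ValueError(f"indices out of range [0, {expected_total}): {sorted(bad)}")
    return set(range(expected_total)) - recovered


# ---------------------------------------------------------------------------
# per-strand inner cascade


def _split_stages(
    spec: PipelineSpec,
) -> tuple[list[BinaryStage], TranscodeStage, list[SiteStage]]:
    binaries = [s for s in spec.inner_stages if isinstance(s, BinaryStage)]
    transcoder = next(
        s for s in spec.inner_stages if isinstance(s, TranscodeStage)
    )
    sites = [s for s in spec.inner_stages if isinstance(s, SiteStage)]
    return binaries, transcoder, sites


def inner_encode(spec: PipelineSpec, raw: bytes) -> tuple[str, dict[str, object]]:
    """Run the single-strand cascade forward; returns the DNA string and the
    state snapshots at every probe attachment point of the spec."""
    binaries, transcoder, sites = _split_stages(spec)
    points = {p.point for p in spec.probes}
    snaps: dict[str, object] = {}
    if "pre_inner" in points:
        snaps["pre_inner"] = raw
    buf = raw
    for st in binaries:
        buf = st.encode(buf)
    if "post_binary" in points:
        snaps["post_binary"] = buf
    dna = transcoder.encode(buf)
    if "post_transcode" in points:
        snaps["post_transcode"] = dna
    for st in sites:
        dna = st.encode(dna)
    if "final" in points:
        snaps["final"] = dna
    return dna, snaps


def inner_decode(spec: PipelineSpec, dna: str) -> DecodeOutcome:
    """Reverse the single-strand cascade; every failure is a DecodeOutcome
    state, never an exception."""
    binaries, transcoder, sites = _split_stages(spec)
    for st in reversed(sites):
        stripped, status = st.decode(dna)
        if status is not DecodeStatus.SUCCESS:
            return DecodeOutcome(status=DecodeStatus.DETECTED_FAILURE)
        dna = stripped
    buf, status = transcoder.decode(dna)
    if status is not DecodeStatus.SUCCESS:
        return DecodeOutcome(status=DecodeStatus.DETECTED_FAILURE)
    for st in reversed(binaries):
        buf, status = st.decode(buf)
        if status is not DecodeStatus.SUCCESS:
            return DecodeOutcome(status=DecodeStatus.DETECTED_FAILURE)
    if len(buf) != spec.serialized_bytes:
        return DecodeOutcome(status=DecodeStatus.DETECTED_FAILURE)
    return DecodeOutcome(
        status=DecodeStatus.SUCCESS,
        recovered=IndexedSequence.deserialize(buf, spec.index_width),
    )


# ---------------------------------------------------------------------------
# whole-file drivers


def encode(spec: PipelineSpec, data: bytes) -> list[EncodedStrand]:
    """Encode a byte block into a strand library (data + outer parity)."""
    violations = validate_pipeline(spec)
    if violations:
        raise PipelineValidationError(violations)
    if len(spec.outer_stages) > 1:
        raise NotImplementedError(
            "cascaded outer codes are interface-only: exactly one outer stage "
            "is supported (see OuterRSStage contract)"
        )
    packets = partition_file(data, spec.payload_bytes, spec.strands_per_packet)
    if spec.outer_stages:
        for p in packets:
            outer_rs_encode(p, spec.outer_stages[0].n_parity_strands)
    indexed = assign_indices(packets, spec.index_width)
    strands: list[EncodedStrand] = []
    for seq in indexed:
        try:
            dna, snaps = inner_encode(spec, seq.serialize())
        except Exception as exc:  # pragma: no cover - surfaced with context
            raise RuntimeError(
                f"encode failed at strand {seq.index}: {exc}"
            ) from exc
        if not dna:
            raise RuntimeError(f"strand {seq.index}: empty DNA after encode")
        strands.append(
            EncodedStrand(
                dna=dna,
                origin_index=seq.index,
                is_parity=seq.is_parity,
                truth_snapshots=snaps,
            )
        )
    return strands


def file_layout(
    spec: PipelineSpec, n_data_strands: int
) -> tuple[int, int, int]:
    """(n_packets, parity_per_packet, expected_total) for a given data size."""
    n_packets = math.ceil(n_data_strands / spec.strands_per_packet)
    c = spec.outer_parity_strands
    return n_packets, c, n_data_strands + n_packets * c


def _n_data_from_total(spec: PipelineSpec, expected_total: int) -> int:
    c = spec.outer_parity_strands
    if c == 0:
        return expected_total
    for n_packets in range(1, expected_total + 1):
        n_data = expected_total - n_packets * c
        if n_data < 1:
            break
        if math.ceil(n_data / spec.strands_per_packet) == n_packets:
            return n_data
    raise ValueError(
        f"expected_total={expected_total} is inconsistent with the packet layout"
    )


def _consolidate(
    spec: PipelineSpec,
    reads: Sequence[str],
    origins: Optional[Sequence[int]],
    expected_total: int,
    stats: RunStats,
) -> dict[int, DecodeOutcome]:
    """Reduce noisy reads to one DecodeOutcome per decoded strand index."""
    mode = spec.consolidation_mode
    per_index: dict[int, list[DecodeOutcome]] = {}

    def route(outcome: DecodeOutcome) -> None:
        if outcome.status is not DecodeStatus.SUCCESS:
            stats.incr("inner_detected_failures")
            return
        idx = outcome.recovered.index
        if idx >= expected_total or len(outcome.recovered.payload) != spec.payload_bytes:
            stats.incr("invalid_index_dropped")
            return
        per_index.setdefault(idx, []).append(outcome)

    if mode in ("pre_inner_msa", "both"):
        if origins is None:
            raise ValueError(
                "pre-inner MSA consolidation requires ground-truth origins "
                "(ideal clustering); supply origins= or use post_inner_vote"
            )
        clusters = cluster_ideal(list(zip(reads, origins)))
        stats.incr("clusters_formed", len(clusters))
        for cl in clusters:
            consensus = msa_consensus(cl)
            route(inner_decode(spec, consensus))
    else:
        for dna in reads:
            route(inner_decode(spec, dna))

    consolidated: dict[int, DecodeOutcome] = {}
    for idx, outcomes in per_index.items():
        if mode == "none":
            consolidated[idx] = outcomes[0]
        else:
            consolidated[idx] = vote_decoded(outcomes)
    return consolidated


def decode(
    spec: PipelineSpec,
    reads: Sequence[str],
    expected_total: int,
    *,
    origins: Optional[Sequence[int]] = None,
    original_length: Optional[int] = None,
) -> tuple[bytes, RunStats]:
    """Decode a noisy read set back into the stored byte block.

    ``expected_total`` is the number of encoded strands including outer
    parity. ``origins`` (ground-truth identity per read) enables ideal
    clustering and is required for the MSA consolidation modes.
    On unrecoverable outer decode the best-effort bytes are returned and
    ``file_failure`` is set in the stats.
    """
    out, stats, _ = decode_detailed(
        spec, reads, expected_total, origins=origins, original_length=original_length
    )
    return out, stats


def decode_detailed(
    spec: PipelineSpec,
    reads: Sequence[str],
    expected_total: int,
    *,
    origins: Optional[Sequence[int]] = None,
    original_length: Optional[int] = None,
) -> tuple[bytes, RunStats, dict[int, DecodeOutcome]]:
    """Like :func:`decode`, additionally returning the consolidated
    per-index outcomes (used by the fault-injection driver to classify
    successes vs silent corruptions against ground truth)."""
    stats = RunStats()
    stats.incr("reads_in", len(reads))
    n_data = _n_data_from_total(spec, expected_total)
    n_packets, c, _ = file_layout(spec, n_data)

    consolidated = _consolidate(spec, reads, origins, expected_total, stats)
    recovered_payloads = {idx: o.recovered.payload for idx, o in consolidated.items()}
    stats.incr("strands_recovered", len(recovered_payloads))
    erased = infer_erasures(set(recovered_payloads), expected_total)
    stats.incr("consolidation_erasures", len(erased))

    out = bytearray()
    file_failed = False
    for p in range(n_packets):
        lo = p * spec.strands_per_packet
        hi = min(lo + spec.strands_per_packet, n_data)
        k_p = hi - lo
        slots = list(range(lo, hi)) + [
            n_data + p * c + j for j in range(c)
        ]
        rows = [recovered_payloads.get(g) for g in slots]
        if c > 0:
            data_rows, status = outer_rs_decode(rows, c, spec.payload_bytes)
            if status is not DecodeStatus.SUCCESS:
                file_failed = True
                stats.incr("outer_packet_failures")
        else:
            data_rows = [
                r if r is not None else bytes(spec.payload_bytes)
                for r in rows[:k_p]
            ]
            if any(r is None for r in rows[:k_p]):
                file_failed = True
                stats.incr("outer_packet_failures")
        for r in data_rows:
            out.extend(r)
    if original_length is not None:
        out = out[:original_length]
    stats.incr("file_failure", int(file_failed))
    return bytes(out), stats, consolidated
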