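"""Factories for the three bundled case-study pipelines.

* ``rs_pipeline`` — whitening, per-strand Reed-Solomon over GF(2^8) covering
  the index and payload, dense 2 bits/base transcoding; strand errors are
  resolved by clustering + star-MSA consensus before the inner decode.
* ``hedges_pipeline`` — hash-convolutional transcoding only; each sequenced
  copy is decoded independently and survivors are voted byte-wise.
* ``hedges_msa_pipeline`` — the convolutional code applied once to the MSA
  consensus of each cluster.

With a 4-byte index and an (x, y) inner Reed-Solomon configuration summing
to x + y + 4 = 60 bytes, RS-pipeline strands are exactly 240 bases at
2 bits/base — the strand-length regime practical synthesis targets.
"""

from __future__ import annotations

from typing import Optional

from .codecs import (
    FunctionalSites,
    InnerRS,
    Randomizer,
    Rot3Transcoder,
    SiteAdder,
    TwoBitTranscoder,
)
from .hedges import HedgesConfig, HedgesTranscoder
from .pipeline import OuterRSStage, PipelineSpec
from .rs import RSConfig

#: Inner configurations of the bundled case study: (parity bytes, data bytes)
RS_INNER_CONFIGS = [(1, 55), (9, 47), (14, 42), (28, 28)]
#: (rate, payload bytes per strand) pairs for the convolutional pipelines
HEDGES_INNER_CONFIGS = [(0.167, 4), (0.25, 9), (0.5, 24), (0.75, 39)]


def rs_pipeline(
    n_parity: int,
    payload_bytes: int,
    *,
    index_width: int = 4,
    strands_per_packet: int = 200,
    outer_parity_strands: int = 0,
    sites: Optional[FunctionalSites] = None,
    randomize_seed: int = 0xD5A,
    consolidation_mode: str = "pre_inner_msa",
    name: Optional[str] = None,
) -> PipelineSpec:
    """Randomize -> inner RS(n_parity over index+payload) -> 2-bit transcode."""
    stages = [
        Randomizer(randomize_seed),
        InnerRS(RSConfig(n_parity, index_width + payload_bytes)),
        TwoBitTranscoder(),
    ]
    if sites is not None:
        stages.append(SiteAdder(sites))
    return PipelineSpec(
        inner_stages=stages,
        payload_bytes=payload_bytes,
        index_width=index_width,
        strands_per_packet=strands_per_packet,
        outer_stages=[OuterRSStage(outer_parity_strands)] if outer_parity_strands else [],
        consolidation_mode=consolidation_mode,
        name=name or f"RS({n_parity},{payload_bytes})",
    )


def _hedges_spec(
    rate: float,
    payload_bytes: int,
    *,
    index_width: int,
    strands_per_packet: int,
    outer_parity_strands: int,
    beam_width: int,
    salt: int,
    sites: Optional[FunctionalSites],
    consolidation_mode: str,
    name: str,
) -> PipelineSpec:
    cfg = HedgesConfig(rate=rate, beam_width=beam_width)
    stages = [HedgesTranscoder(cfg, index_width + payload_bytes, salt=salt)]
    if sites is not None:
        stages.append(SiteAdder(sites))
    return PipelineSpec(
        inner_stages=stages,
        payload_bytes=payload_bytes,
        index_width=index_width,
        strands_per_packet=strands_per_packet,
        outer_stages=[OuterRSStage(outer_parity_strands)] if outer_parity_strands else [],
        consolidation_mode=consolidation_mode,
        name=name,
    )


def hedges_pipeline(
    rate: float,
    payload_bytes: int,
    *,
    index_width: int = 4,
    strands_per_packet: int = 200,
    outer_parity_strands: int = 0,
    beam_width: int = 16,
    salt: int = 0,
    sites: Optional[FunctionalSites] = None,
) -> PipelineSpec:
    """Convolutional inner code, each copy decoded independently + voted."""
    return _hedges_spec(
        rate,
        payload_bytes,
        index_width=index_width,
        strands_per_packet=strands_per_packet,
        outer_parity_strands=outer_parity_strands,
        beam_width=beam_width,
        salt=salt,
        sites=sites,
        consolidation_mode="post_inner_vote",
        name=f"HEDGES({rate},{payload_bytes})",
    )


def hedges_msa_pipeline(
    rate: float,
    payload_bytes: int,
    *,
    index_width: int = 4,
    strands_per_packet: int = 200,
    outer_parity_strands: int = 0,
    beam_width: int = 16,
    salt: int = 0,
    sites: Optional[FunctionalSites] = None,
) -> PipelineSpec:
    """Convolutional inner code applied once to the MSA consensus."""
    return _hedges_spec(
        rate,
        payload_bytes,
        index_width=index_width,
        strands_per_packet=strands_per_packet,
        outer_parity_strands=outer_parity_strands,
        beam_width=beam_width,
        salt=salt,
        sites=sites,
        consolidation_mode="pre_inner_msa",
        name=f"HEDGES-MSA({rate},{payload_bytes})",
    )


def rot3_pipeline(
    payload_bytes: int,
    *,
    index_width: int = 4,
    strands_per_packet: int = 200,
    outer_parity_strands: int = 0,
    sites: Optional[FunctionalSites] = None,
) -> PipelineSpec:
    """Homopolymer-free base-3 rotation transcoding, no inner byte code."""
    stages = [Rot3Transcoder()]
    if sites is not None:
        stages.append(SiteAdder(sites))
    return PipelineSpec(
        inner_stages=stages,
        payload_bytes=payload_bytes,
        index_width=index_width,
        strands_per_packet=strands_per_packet,
        outer_stages=[OuterRSStage(outer_parity_strands)] if outer_parity_strands else [],
        consolidation_mode="pre_inner_msa",
        name=f"ROT3({payload_bytes})",
    )
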