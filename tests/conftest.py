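import random

import pytest

from strandsim.pipelines import (
    hedges_msa_pipeline,
    hedges_pipeline,
    rs_pipeline,
    rot3_pipeline,
)


@pytest.fixture
def rng():
    return random.Random(0xBEEF)


def all_bundled_pipelines(**kwargs):
    """Small-packet variants of every bundled pipeline family."""
    return [
        rs_pipeline(9, 47, strands_per_packet=10, outer_parity_strands=2, **kwargs),
        rs_pipeline(1, 55, strands_per_packet=10, outer_parity_strands=2, **kwargs),
        hedges_pipeline(0.5, 24, strands_per_packet=10, outer_parity_strands=2),
        hedges_msa_pipeline(0.25, 9, strands_per_packet=10, outer_parity_strands=2),
        rot3_pipeline(30, strands_per_packet=10, outer_parity_strands=2),
    ]


@pytest.fixture(params=range(5), ids=["rs947", "rs155", "hedges", "hedgesmsa", "rot3"])
def bundled_spec(request):
    return all_bundled_pipelines()[request.param]
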