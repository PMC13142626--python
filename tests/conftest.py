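import random

import pytest

from vmusdbg import (
    UniquenessConfig,
    build_graph,
    extract_mus,
    toy_genome,
    toy_read_set,
)

TOY_MUS = ["AC", "AG", "AT", "CT", "GCA", "TA", "TG"]


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture(scope="session")
def toy_anchors():
    return extract_mus(toy_genome(), UniquenessConfig(scope="genome", circular=True))


@pytest.fixture(scope="session")
def toy_reads():
    return toy_read_set()


@pytest.fixture(scope="session")
def toy_graph(toy_reads, toy_anchors):
    """The worked-example graph; treat as read-only (copy before mutating)."""
    return build_graph(toy_reads, toy_anchors)
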