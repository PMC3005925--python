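"""Shared fixtures: the synthetic backbone, canonical parts and constructs.

Everything is generated programmatically at test time; there are no stored
sequence files. Session scope keeps the (cheap but repeated) construct
assembly from dominating the run.
"""

import random

import pytest

from opergate import (
    build_plasmid,
    build_synthetic_backbone,
    builtin_enzymes,
    lac_operator_part,
    luxr_cassette_part,
    placq_part,
)


@pytest.fixture(scope="session")
def enzymes():
    return {e.name: e for e in builtin_enzymes()}


@pytest.fixture(scope="session")
def backbone():
    """The virgin synthetic platform plasmid (pSB-GFP stand-in), seed 0."""
    return build_synthetic_backbone()


@pytest.fixture(scope="session")
def constructs():
    """All six named plasmids of the study, assembled from scratch."""
    return {
        name: build_plasmid(name, seed=0)
        for name in (
            "pSB-GFP",
            "Placq-GFP",
            "Placq-LacI-GFP",
            "Placq-LacItandem-GFP",
            "PLuxR-GFP",
            "PLuxR-LacItandem-GFP",
        )
    }


@pytest.fixture()
def lac_part():
    return lac_operator_part()


@pytest.fixture()
def placq():
    return placq_part()


@pytest.fixture()
def luxr():
    return luxr_cassette_part()


@pytest.fixture()
def rng():
    return random.Random(20100)


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))
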