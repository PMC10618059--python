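import pytest

from booldoi import SeedSet, build_gtn, toy_network


@pytest.fixture(scope="session")
def toy():
    """Four-node toy network: inputs a, b, c; d = (a AND c) OR (b AND c)."""
    return toy_network()


@pytest.fixture(scope="session")
def toy_gtns(toy):
    return {rep: build_gtn(toy, rep) for rep in ("LUT", "DNF", "SR")}


@pytest.fixture(scope="session")
def seeds_ac():
    """The worked-example seed set: a and c pinned active."""
    return SeedSet.from_string("a=1,c=1")
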