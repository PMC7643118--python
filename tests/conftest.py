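import pytest

from hrdscar import InMemoryGenome, make_fixture_genome


@pytest.fixture(scope="session")
def genome10k() -> InMemoryGenome:
    """A 10 kb deterministic random genome shared across tests."""
    return make_fixture_genome(10_000, gc=0.41, seed=42)


def make_genome(seq: str, contig: str = "chr1") -> InMemoryGenome:
    """Hand-built genome for examples with known flanking sequence."""
    return InMemoryGenome({contig: seq})
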