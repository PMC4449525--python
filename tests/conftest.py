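import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from alfalign.index import build_index
from alfalign.simulate import simulate_genome


@pytest.fixture
def rng():
    return random.Random(0)


@pytest.fixture(scope="session")
def genome_10k():
    return simulate_genome(10_000, 1234)


@pytest.fixture(scope="session")
def index_10k(genome_10k):
    return build_index(genome_10k, 4)


@pytest.fixture(scope="session")
def genome_100k():
    """The desk-scale stand-in for a reference genome used by the
    end-to-end tests."""
    return simulate_genome(100_000, 42)


@pytest.fixture(scope="session")
def index_100k(genome_100k):
    return build_index(genome_100k, 12)
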