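import numpy as np
import pytest

from gapseek.engine import analyze_genome
from gapseek.synthetic import FixtureSpec, build_universe


@pytest.fixture(scope="session")
def universe():
    """Full 5-genome universe with markers and a known-gap catalog."""
    return build_universe(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def mini_universe():
    """Single-genome universe without markers, for fast engine tests."""
    return build_universe(
        FixtureSpec(seed=5, genome_count=1, marker_count=0, marker_identities=(1.0,))
    )


@pytest.fixture(scope="session")
def mini_result(mini_universe):
    u = mini_universe
    return analyze_genome("G00", u.proteomes["G00"], u.pathways, u.db)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
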