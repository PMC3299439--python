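import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gapml import parse_newick, printed_alignment_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def printed_alignment():
    return printed_alignment_fixture()


@pytest.fixture(scope="session")
def quartet():
    """Unrooted 4-taxon tree ab|cd with mixed edge parameters."""
    return parse_newick("((a:0.1,b:0.2):0.15,c:0.05,d:0.3);")


@pytest.fixture(scope="session")
def five_taxon_tree():
    """The true tree used by the simulation studies: ((a,b),(c,d),e)."""
    return parse_newick("((a,b),(c,d),e);")


@pytest.fixture()
def rng():
    return np.random.default_rng(20120313)
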