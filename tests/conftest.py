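import numpy as np
import pytest

import crnkit as ck
from crnkit.io import FIXTURE_NAMES


@pytest.fixture(scope="session")
def fixtures():
    """All bundled models, built once per session."""
    return {name: ck.fixture_model(name) for name in FIXTURE_NAMES}


@pytest.fixture
def brusselator(fixtures):
    return fixtures["brusselator"]


@pytest.fixture
def birth_death(fixtures):
    return fixtures["birth_death"]


@pytest.fixture
def dimerization(fixtures):
    return fixtures["dimerization"]


def random_positive_states(n_species: int, n: int, seed: int, scale: float = 10.0):
    gen = np.random.default_rng(seed)
    return scale * gen.random((n, n_species)) + 0.1


def random_integer_states(n_species: int, n: int, seed: int, high: int = 50):
    gen = np.random.default_rng(seed)
    return gen.integers(0, high, size=(n, n_species))


MINIMAL_NET = """\
# synthetic minimal BioNetGen-style network (hand-written fixture)
begin parameters
  1 k1 2.0
  2 k2 0.5*k1
end parameters
begin species
  1 A(b) 100
  2 B(a~P) 0
end species
begin reactions
  1 1 2 k1
  2 1,1 2 2*k2
  3 2 0 k2
end reactions
"""


@pytest.fixture
def minimal_net(tmp_path):
    p = tmp_path / "minimal.net"
    p.write_text(MINIMAL_NET)
    return p
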