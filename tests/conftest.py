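import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import latagg as lg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def model():
    return lg.InteractionModel()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_antiparallel_dimer(box=None):
    """Two extended chains, antiparallel and in register, one lattice apart."""
    box = box or lg.SimulationBox(12, 12, 12)
    seq = lg.parse_sequence(lg.DEFAULT_SEQUENCE)
    M = len(seq)
    chains = np.zeros((2, M, 3), dtype=np.int64)
    for i in range(M):
        chains[0, i] = (2 + i, 4, 4)
        chains[1, i] = (2 + (M - 1 - i), 5, 4)
    return lg.SystemState(sequence=seq, chains=chains, box=box)


@pytest.fixture
def antiparallel_dimer():
    return make_antiparallel_dimer()
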