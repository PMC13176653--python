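import numpy as np
import pytest

from ifnscope.synthetic_data import (
    SimConfig,
    build_training_set,
    emit_hits,
    simulate_pangenome,
)


@pytest.fixture(scope="session")
def pangenome():
    """Default 18-species pangenome with sequences (seed fixed for the suite)."""
    return simulate_pangenome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def fast_pangenome():
    """Annotation-only twin of the default pangenome."""
    return simulate_pangenome(SimConfig(seed=11), sequences=False)


@pytest.fixture(scope="session")
def pangenome_hits(pangenome):
    return emit_hits(pangenome, jitter=30, seed=0)


@pytest.fixture(scope="session")
def training_set(pangenome):
    return build_training_set(pangenome, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
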