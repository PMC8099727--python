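import numpy as np
import pytest

from sunkasm import simulate
from sunkasm.config import RunConfig
from sunkasm.seq import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference five-layer mirrored array (~150-kb array, 25-kb flanks)."""
    return simulate.simulate_layered_array(simulate.default_array_spec(seed=0))


@pytest.fixture(scope="session")
def pipeline_bundle():
    """One full synthetic pipeline run, shared by the tests that inspect it."""
    from sunkasm.pipeline import run_pipeline

    return run_pipeline(RunConfig(seed=1))


@pytest.fixture(scope="session")
def printed_monomers():
    from sunkasm.hor import load_default_monomers

    return load_default_monomers()


@pytest.fixture
def small_genome():
    return random_dna(10_000, np.random.default_rng(7))
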