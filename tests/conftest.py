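import numpy as np
import pytest

from annotkit.synthetic_data import GenomeSimSpec, simulate_annotated_genome


@pytest.fixture(scope="session")
def sim_genome():
    """One shared simulated genome with planted truth (deterministic)."""
    return simulate_annotated_genome(GenomeSimSpec(seed=3))


@pytest.fixture(scope="session")
def sim_genome_dir(sim_genome, tmp_path_factory):
    out = tmp_path_factory.mktemp("simgenome")
    sim_genome.write(out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
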