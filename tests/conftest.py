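import numpy as np
import pytest

from snporf import synthetic_data as sd
from snporf import transcriptome as tr


@pytest.fixture(scope="session")
def small_sim():
    """A 40-gene synthetic genome with diversity track and truth manifest."""
    params = sd.SimulationParams(n_genes=40, seed=11)
    genome, annotation, manifest = sd.simulate_genome(params)
    track = sd.simulate_diversity(genome, annotation, manifest, params)
    return params, genome, annotation, manifest, track


@pytest.fixture(scope="session")
def small_transcripts(small_sim):
    _, genome, annotation, _, _ = small_sim
    return tr.build_transcripts(genome, annotation)


@pytest.fixture(scope="session")
def default_sim():
    """The default study-condition genome: 200 genes, fixed seed."""
    params = sd.SimulationParams(n_genes=200, seed=1)
    genome, annotation, manifest = sd.simulate_genome(params)
    track = sd.simulate_diversity(genome, annotation, manifest, params)
    return params, genome, annotation, manifest, track


@pytest.fixture
def rng():
    return np.random.default_rng(0)
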