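import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nt_scheme():
    from acaryopan.alignment import ScoringScheme
    return ScoringScheme.nucleotide()


@pytest.fixture(scope="session")
def prot_scheme():
    from acaryopan.alignment import ScoringScheme
    return ScoringScheme.protein()


@pytest.fixture(scope="session")
def small_collection():
    """A 4+2-genome simulated collection shared across tests."""
    from acaryopan.synthetic import SimulationConfig, simulate_collection
    cfg = SimulationConfig(n_ingroup=4, n_outgroup=2, n_ancestral_genes=30,
                           mean_gene_len=300, seed=7)
    tree, genomes, truth = simulate_collection(cfg)
    return cfg, tree, genomes, truth


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def random_protein(rng: np.random.Generator, n: int) -> str:
    aa = "ARNDCQEGHILKMFPSTWYV"
    return "".join(aa[i] for i in rng.integers(0, 20, n))
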