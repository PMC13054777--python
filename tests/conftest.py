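import numpy as np
import pytest
from hypothesis import settings

from stancekin.phylo import parse_newick

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")
from stancekin.simulate import GeneratorConfig, generate_species_dataset, simulate_yule_tree


@pytest.fixture
def three_taxon_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-species synthetic dataset shared by pipeline-level tests."""
    cfg = GeneratorConfig(n_species=60, seed=12345)
    species, truth, tree = generate_species_dataset(cfg)
    return cfg, species, truth, tree


@pytest.fixture(scope="session")
def yule_30():
    return simulate_yule_tree(30, 1.0, rng=np.random.default_rng(11))
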