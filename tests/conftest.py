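import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synclock as sc

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture
def circular8():
    """Circular reference genome g1..g8."""
    return sc.GeneOrder("A", tuple(f"g{i}" for i in range(1, 9)), "circular")


@pytest.fixture
def circular8_swapped():
    """circular8 with g4 and g7 exchanged."""
    return sc.GeneOrder("B", ("g1", "g2", "g3", "g7", "g5", "g6", "g4", "g8"), "circular")


@pytest.fixture(scope="session")
def default_scenario():
    """One default synthetic study with a single injected 16S transfer."""
    config = sc.ScenarioConfig(seed=0, hgt_injections=(("C1_S1", "C2"),))
    genomes, seqs, truth = sc.generate_scenario(config)
    return config, genomes, seqs, truth


@pytest.fixture(scope="session")
def default_study(default_scenario):
    """Full pipeline result on the default scenario."""
    config, genomes, seqs, truth = default_scenario
    result = sc.run_study(
        genomes, seqs,
        synteny_params=sc.SyntenyParams(k=config.k),
        gene_order_model=sc.ModelParams(n=config.genome_size, k=config.k),
        outlier_config=sc.OutlierConfig(seed=0),
    )
    return config, truth, result


def random_gene_order(rng: np.random.Generator, n: int, genome_id: str = "G",
                      topology: str = "circular") -> sc.GeneOrder:
    """Random permutation genome with unique labels."""
    labels = [f"g{i}" for i in rng.permutation(n)]
    return sc.GeneOrder(genome_id, tuple(labels), topology)
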