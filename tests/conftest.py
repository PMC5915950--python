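import math

import pytest

from homeokit.simulate import (
    SimConfig,
    simulate_ancestral_genomes,
    simulate_counts,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=101,
        genome_length=60_000,
        n_genes=30,
        divergence_rate=0.005,
        read_length=150,
        n_reads=1_000,
        error_rate=0.002,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """(genome_a, genome_b, genes, snp_truth) for a small deterministic run."""
    return simulate_ancestral_genomes(small_config)


@pytest.fixture(scope="session")
def small_reads(small_study, small_config):
    genome_a, genome_b, _, _ = small_study
    return simulate_reads(genome_a, genome_b, small_config)


@pytest.fixture(scope="session")
def planted_config() -> SimConfig:
    """Config sized so every planted gene is comfortably expressed."""
    return SimConfig(
        seed=202,
        genome_length=900_000,
        n_genes=400,
        dispersion=0.02,
        fold_change=4.0,
        mu_log=math.log(3e-4),
        sigma_log=0.4,
        baseline_floor=1.2e-4,
    )


@pytest.fixture(scope="session")
def planted_counts(planted_config):
    _, _, genes, _ = simulate_ancestral_genomes(planted_config)
    return simulate_counts(genes, planted_config)
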