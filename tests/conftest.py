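"""Shared fixtures: small simulated datasets and consensus runs.

The heavyweight fixtures (iterative consensus runs) are session-scoped so
several test modules can assert against the same assembly without paying
for it repeatedly.
"""

import pytest

from porebench.consensus import ConsensusParams, iterative_consensus
from porebench.simulate import (SimulationConfig, generate_reference,
                                simulate_reads)


@pytest.fixture(scope="session")
def random_error_sim():
    """20 kbp / depth 20 simulation with only the random 5% error channel."""
    cfg = SimulationConfig(genome_bp=20_000, depth=20, read_len_mean=3000,
                           read_len_sd=800, seed=7)
    truth = generate_reference(cfg)
    reads, ledgers = simulate_reads(truth, cfg)
    truth.ledgers = ledgers
    return cfg, truth, reads


@pytest.fixture(scope="session")
def random_error_consensus(random_error_sim):
    """Iterative consensus of the random-error simulation."""
    _, truth, reads = random_error_sim
    return iterative_consensus(truth.reference, reads,
                               ConsensusParams(seed=1), circular=True)


@pytest.fixture(scope="session")
def systematic_sim():
    """Simulation with strong systematic channels: Dcm miscalls at 90% of
    reads per site and homopolymer slips at 90%, over 100 planted motifs."""
    cfg = SimulationConfig(genome_bp=20_000, depth=20, read_len_mean=3000,
                           read_len_sd=800, dcm_error_rate=0.9,
                           homopolymer_slip_rate=0.9, seed=11)
    truth = generate_reference(cfg)
    reads, ledgers = simulate_reads(truth, cfg)
    truth.ledgers = ledgers
    return cfg, truth, reads


@pytest.fixture(scope="session")
def systematic_consensus(systematic_sim):
    _, truth, reads = systematic_sim
    return iterative_consensus(truth.reference, reads,
                               ConsensusParams(seed=2), circular=True)
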