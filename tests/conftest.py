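import numpy as np
import pytest

from phasecall.diploid_simulator import (
    SimulationConfig,
    simulate_diploid,
    simulate_reads,
)


@pytest.fixture(scope="session")
def clean_sim():
    """Small diploid simulation with low (5%) error and 30x total depth."""
    config = SimulationConfig(
        ref_length=20_000,
        seed=11,
        depth_per_haplotype=15,
        accuracy_mean=0.95,
        accuracy_sd=0.03,
    )
    truth = simulate_diploid(config)
    reads = simulate_reads(truth, config)
    return config, truth, reads


@pytest.fixture(scope="session")
def noiseless_sim():
    """Error-free reads at 20x per haplotype."""
    config = SimulationConfig(
        ref_length=20_000,
        seed=13,
        depth_per_haplotype=20,
        accuracy_mean=1.0,
        accuracy_sd=1e-9,
    )
    truth = simulate_diploid(config)
    reads = simulate_reads(truth, config)
    return config, truth, reads


def random_read_observations(rng, n_sites=4, n_reads=8, error=0.1, qual=10.0):
    """Random diploid phasing instance with known haplotype alleles."""
    from phasecall.sew_phase import ReadObservation

    hap = rng.integers(0, 2, size=n_sites)
    reads = []
    for i in range(n_reads):
        h = i % 2
        true = hap if h == 0 else 1 - hap
        flip = rng.random(n_sites) < error
        obs = np.where(flip, 1 - true, true)
        reads.append(
            ReadObservation(
                index=i,
                strand="+" if rng.random() < 0.5 else "-",
                site_indices=np.arange(n_sites),
                alleles=obs,
                quals=np.full(n_sites, qual),
            )
        )
    return reads, hap
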