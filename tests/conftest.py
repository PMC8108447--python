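import pytest

from pseudotx import SimulationConfig, run_cohort, simulate


@pytest.fixture(scope="session")
def noise_free_sim():
    """Default study conditions: no divergence, no jitter, seed 1."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_sim):
    sim = noise_free_sim
    return run_cohort(
        sim.transcripts,
        sim.genes,
        sim.pseudogene_records,
        sim.genome,
        sim.cage_peaks,
        cdnas=sim.cdnas,
        ortholog_windows=sim.ortholog_windows,
    )
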