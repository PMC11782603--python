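import pytest

from secmx.pipeline import run_pipeline
from secmx.simulate import GeneratorConfig, simulate_experiment


@pytest.fixture(scope="session")
def sim_clean():
    """Small noise-free experiment: every stage should be exact on it."""
    cfg = GeneratorConfig(seed=7, n_proteins=40, noise_sigma=0.0, missing_rate=0.0)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def result_clean(sim_clean):
    return run_pipeline(
        sim_clean.records, sim_clean.design, sim_clean.standard, sim_clean.monomer_masses
    )


@pytest.fixture(scope="session")
def sim_noisy():
    cfg = GeneratorConfig(seed=13, n_proteins=40, noise_sigma=0.1, missing_rate=0.02)
    return simulate_experiment(cfg)
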