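import pytest

from skinflow import SimConfig, simulate_and_classify


@pytest.fixture(scope="session")
def small_run():
    """A 300-gene simulated experiment pushed through the full pipeline."""
    cfg = SimConfig(n_genes=300, n_bootstraps=100, seed=42)
    return simulate_and_classify(cfg)


@pytest.fixture(scope="session")
def small_model(small_run):
    return small_run.result.model
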