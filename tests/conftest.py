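import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from polyacomp.pipeline import PipelineConfig
from polyacomp.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def clean_sim():
    """Small clean synthetic dataset (no artifacts, no duplicates)."""
    cfg = SimConfig(seed=11, n_sites=60, n_chroms=2, chrom_len=30_000)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(min_sites=10)
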