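import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from tps3d import PhantomConfig, PipelineConfig, PositivityProfile, generate_phantom, run_pipeline


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Desk-scale phantom: 160 μm square field, 60 μm deep, 120 cells."""
    return PhantomConfig(
        field_size_um=(160.0, 160.0),
        depth_um=60.0,
        n_cells=120,
        seed=11,
        positivity_profile=PositivityProfile(kind="constant", p=0.3),
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config)


@pytest.fixture(scope="session")
def noise_free_config(small_config) -> PhantomConfig:
    return small_config.model_copy(update={"snr": None})


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_config):
    return generate_phantom(noise_free_config)


@pytest.fixture(scope="session")
def small_result(small_phantom):
    volume, _ = small_phantom
    return run_pipeline(volume, PipelineConfig(masker="constant"))
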