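import numpy as np
import pytest

from sersquant import GeneratorConfig, generate_plate, make_default_design


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A fast plate config: tiny raster, three concentrations, 3 replicates."""
    return GeneratorConfig(
        raster_lines=6,
        raster_per_line=7,
        concentrations=(5000.0, 625.0, 78.0),
        replicate_wells_per_sample=3,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_plate(small_config):
    design = make_default_design(small_config, rows=4, cols=3)
    return generate_plate(design, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
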