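import numpy as np
import pandas as pd
import pytest

from traitsoil import PlotGeometry, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_geometry() -> PlotGeometry:
    return PlotGeometry(100.0, 100.0, 20.0)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A reduced plot that keeps the whole-pipeline tests fast."""
    return SyntheticConfig(
        width=400.0, height=300.0, resolution=10.0,
        n_species=25, n_stems=2000,
        basal_spacing=50.0, offsets=(2.0, 5.0, 15.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def toy_samples() -> pd.DataFrame:
    """Five irregular soil samples of one variable on a 100 x 100 m plot."""
    return pd.DataFrame({
        "x": [10.0, 35.0, 60.0, 80.0, 55.0],
        "y": [15.0, 70.0, 40.0, 85.0, 10.0],
        "v": [1.2, -0.4, 0.8, 2.1, -1.0],
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
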