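import numpy as np
import pytest

from tcellact.synthetic_data import SyntheticScenario, generate_cell


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """Compact but fully featured scenario used across module tests."""
    return SyntheticScenario(
        seed=11,
        duration_s=240.0,
        t_activation_s=120.0,
        img_size_px=96,
        cell_radius_um=4.0,
        area_lag_s=4.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    """One rendered cell (all three modalities), shared across tests."""
    return generate_cell(small_scenario)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
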