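import pytest

from mcdem import (
    MCC_A,
    MCC_A_PSD,
    ContactModelParams,
    LoadingProtocol,
    SimulationConfig,
    effective_properties,
    fit_psd,
    generate_packing,
)


@pytest.fixture(scope="session")
def mcc_a_pair():
    """Pair properties of two median-sized coarse-MCC particles."""
    r50 = MCC_A_PSD.x50 / 2.0
    return effective_properties(MCC_A, r50, MCC_A, r50, ContactModelParams())


@pytest.fixture(scope="session")
def small_packing():
    """A small relaxed RVE used by several dynamics tests (seeded)."""
    return generate_packing((0.4e-3,) * 3, MCC_A_PSD, 0.59, MCC_A, seed=1)


@pytest.fixture(scope="session")
def quarter_psd():
    """Quarter-scale coarse-MCC PSD for cheap multi-particle rigs."""
    return fit_psd(MCC_A_PSD.x10 / 4, MCC_A_PSD.x50 / 4, MCC_A_PSD.x90 / 4)


@pytest.fixture()
def quick_protocol():
    return LoadingProtocol(max_strain=0.3, n_steps=8000, decompress=False)


@pytest.fixture()
def quick_config():
    return SimulationConfig(snapshot_interval=100)
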