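import numpy as np
import pytest

from metacoex import SpeciesTraits, SupplyField, generate_supply


@pytest.fixture(scope="session")
def supply20() -> SupplyField:
    """20-patch log-normal supply field, the standard study setting."""
    return generate_supply(20, 1.0, 1.5, seed=11)


@pytest.fixture(scope="session")
def supply_small() -> SupplyField:
    """Mildly heterogeneous 6-patch field for cheap checks."""
    return generate_supply(6, 1.0, 0.8, seed=4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_traits(rng: np.random.Generator, p_max: float = 0.95) -> SpeciesTraits:
    """Random trait draw with R* in (0.05, 0.95)."""
    b = rng.uniform(0.5, 2.0)
    return SpeciesTraits(
        m=b * rng.uniform(0.05, 0.95),
        b=b,
        Q=rng.uniform(0.5, 2.0),
        p=rng.uniform(0.0, p_max),
    )
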