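import numpy as np
import pytest

from fundusdr import (
    FixtureConfig,
    FundusImage,
    NetworkConfig,
    build_network,
    generate_fixture,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_image():
    """One default 300-px synthetic fundus image with all three signs."""
    return generate_fixture(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def small_model():
    """An untrained (random-init) classifier for 24-px patches."""
    return build_network(
        NetworkConfig(input_side=24, feature_maps=8, fc_units=32), seed=3
    )


@pytest.fixture(scope="session")
def default_model():
    """An untrained classifier at the standard 50-px patch size."""
    return build_network(NetworkConfig(), seed=3)


def make_image(pixels, **kw) -> FundusImage:
    return FundusImage(pixels=np.asarray(pixels, dtype=float), **kw)
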