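import numpy as np
import pytest

from pursuitbayes import (
    DesignSpec,
    NoiseParams,
    ObserverParams,
    PriorParams,
    fixture_observer,
    make_fixture_design,
    simulate_observer,
)


@pytest.fixture(scope="session")
def asymmetric_observer() -> ObserverParams:
    """Reference observer with a noisier pursuit-target channel."""
    return fixture_observer()


@pytest.fixture(scope="session")
def symmetric_observer() -> ObserverParams:
    """Observer with identical channels: every illusion must vanish."""
    noise = NoiseParams(a=0.10, b=0.6, c=0.3)
    return ObserverParams(noise_R=noise, noise_T=noise, prior=PriorParams(2.0))


@pytest.fixture(scope="session")
def constant_noise_observer() -> ObserverParams:
    """Speed-independent noise (a=0): shrinkage has a textbook closed form."""
    return ObserverParams(
        noise_R=NoiseParams(a=1e-12, b=1.0, c=1.0),
        noise_T=NoiseParams(a=1e-12, b=1.0, c=2.0),
        prior=PriorParams(2.0),
    )


@pytest.fixture(scope="session")
def design() -> DesignSpec:
    return make_fixture_design()


@pytest.fixture(scope="session")
def small_design() -> DesignSpec:
    """Down-sized design for fast fitting tests."""
    return DesignSpec(
        standards={"FF": (2.0, 8.0), "EE": (2.0, 8.0), "EF": (8.0,)},
        n_levels=5,
        trials_per_point=30,
    )


@pytest.fixture(scope="session")
def fixture_trials(design, asymmetric_observer):
    return simulate_observer(design, asymmetric_observer, seed=20123)


@pytest.fixture(scope="session")
def small_trials(small_design, asymmetric_observer):
    return simulate_observer(small_design, asymmetric_observer, seed=414)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
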