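import numpy as np
import pytest

from posturo.simulate import ChaoticFixture, chaotic_fixture_series, lyapunov_oracle


@pytest.fixture(scope="session")
def lorenz_fixture() -> ChaoticFixture:
    return ChaoticFixture("LORENZ", {"dt": 0.01}, n_samples=30_000, transient_discard=1_000)


@pytest.fixture(scope="session")
def lorenz_series(lorenz_fixture) -> np.ndarray:
    return chaotic_fixture_series(lorenz_fixture)


@pytest.fixture(scope="session")
def lorenz_benettin_lye() -> float:
    """Benettin tangent-space exponent for the standard Lorenz parameters."""
    oracle_fixture = ChaoticFixture(
        "LORENZ", {"dt": 0.01}, n_samples=200_000, transient_discard=1_000
    )
    return lyapunov_oracle(oracle_fixture)


@pytest.fixture(scope="session")
def logistic_series() -> np.ndarray:
    fixture = ChaoticFixture(
        "LOGISTIC", {"r": 4.0, "x0": 0.3}, n_samples=10_000, transient_discard=100
    )
    return chaotic_fixture_series(fixture)


@pytest.fixture(scope="session")
def period100_sine() -> np.ndarray:
    """5000 samples of a period-100 sine.

    The period is offset by 0.14% so successive cycles sample fresh
    phases; an exactly commensurate period visits only 100 distinct
    values, which degenerates both the joint histogram of the AMI and
    nearest-neighbour geometry.
    """
    t = np.arange(5000)
    return np.sin(2 * np.pi * t / (100.0 * (1 + 1e-3 * np.sqrt(2))))
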