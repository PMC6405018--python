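import logging
import math

import numpy as np
import pytest

from permtest import sign_flip_group_set, symmetric_group_set


@pytest.fixture(autouse=True)
def _quiet_permtest_logger():
    # tests inspect warning records via caplog; keep stderr clean
    logger = logging.getLogger("permtest")
    logger.propagate = True
    handler = logging.NullHandler()
    logger.addHandler(handler)
    yield
    logger.removeHandler(handler)


@pytest.fixture(scope="session")
def sign_flip_3():
    return sign_flip_group_set(3)


@pytest.fixture(scope="session")
def sign_flip_4():
    return sign_flip_group_set(4)


@pytest.fixture(scope="session")
def s3():
    return symmetric_group_set(3)


@pytest.fixture(scope="session")
def s6():
    return symmetric_group_set(6)


def binomial_band(p: float, reps: int, k: float = 3.0) -> float:
    """Half-width of the k-sigma binomial acceptance band around rate p."""
    return k * math.sqrt(p * (1.0 - p) / reps)


@pytest.fixture(scope="session")
def band():
    return binomial_band


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)
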