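"""Shared fixtures: catalogued synthetic cohorts, generated once per session."""

import numpy as np
import pytest

from convbag.synth import make_fixture


@pytest.fixture(scope="session")
def separable_small():
    return make_fixture("separable_small")


@pytest.fixture(scope="session")
def imbalanced_benchmark():
    return make_fixture("imbalanced_benchmark")


@pytest.fixture(scope="session")
def outlier_screen():
    return make_fixture("outlier_screen")


@pytest.fixture(scope="session")
def noisy_benchmark():
    return make_fixture("noisy_benchmark")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
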