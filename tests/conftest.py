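import numpy as np
import pytest

from mutweight import build_matrix, make_fixture


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_matrix(tiny_cohort):
    return build_matrix(tiny_cohort.records, labels=tiny_cohort.labels)


@pytest.fixture(scope="session")
def separable_cohort():
    return make_fixture("separable")


@pytest.fixture(scope="session")
def separable_matrix(separable_cohort):
    return build_matrix(separable_cohort.records, labels=separable_cohort.labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
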