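import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dermtriage.fixtures import make_fixture

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def study_lesions():
    lesions, _ = make_fixture("study_marginals")
    return lesions


@pytest.fixture(scope="session")
def study_patients():
    _, patients = make_fixture("study_marginals")
    return patients


@pytest.fixture(scope="session")
def tiny_lesions():
    lesions, _ = make_fixture("tiny")
    return lesions


@pytest.fixture()
def rng():
    return np.random.default_rng(20240322)
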