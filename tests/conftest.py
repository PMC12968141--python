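import numpy as np
import pytest

from odepinn import make_case_study


@pytest.fixture(scope="session")
def logistic_case():
    return make_case_study("logistic")


@pytest.fixture(scope="session")
def gene_case():
    return make_case_study("gene")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
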