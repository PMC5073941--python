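import numpy as np
import pytest

from gmmkin import builtin_model
from gmmkin.network import FIXTURE_TRUTH


@pytest.fixture(scope="session")
def gene_expression():
    return builtin_model("gene_expression")


@pytest.fixture(scope="session")
def exclusive_switch():
    return builtin_model("exclusive_switch")


@pytest.fixture(scope="session")
def ge_truth():
    return dict(FIXTURE_TRUTH["gene_expression"])


@pytest.fixture(scope="session")
def es_truth():
    return dict(FIXTURE_TRUTH["exclusive_switch"])


@pytest.fixture(scope="session")
def birth_death_text():
    return """
[species]
X 0 high

[reactions]
0 -> X @ c
X -> 0 @ d

[parameters]
c = 2.0 in [0.0, 10.0]
d = 0.5 in [0.0, 10.0]
"""


def pytest_configure(config):
    np.seterr(over="ignore")
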