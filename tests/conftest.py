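import numpy as np
import pytest

from biruni import SynthSpec, generate_features, make_fixture


@pytest.fixture(scope="session")
def tiny_easy():
    """Separable 120 x 20 table (5 informative features, delta=6)."""
    return make_fixture("tiny_easy")


@pytest.fixture(scope="session")
def tiny_hard():
    return make_fixture("tiny_hard")


@pytest.fixture(scope="session")
def fs_table():
    """Recovery battery table: d=50, k=5, delta=4."""
    return generate_features(
        SynthSpec(n_class0=60, n_class1=60, d=50, k=5, delta=4.0, seed=100)
    )
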