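import numpy as np
import pytest

from parbslide.substrate import build_substrate


@pytest.fixture(scope="session")
def sub39():
    return build_substrate("39x_parS")


@pytest.fixture(scope="session")
def sub_ecori39():
    return build_substrate("ecoRI_39x_parS")


@pytest.fixture(scope="session")
def sub2x():
    return build_substrate("2x_parS")


@pytest.fixture(scope="session")
def sub_lambda():
    return build_substrate("lambda_control")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
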