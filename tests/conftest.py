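import numpy as np
import pytest

from sofnet.connectome import YEO17
from sofnet.memory import EncodingHistory, ModelParams, encode

#: The eight selected edge weights of the reference connectivity model,
#: keyed by canonical edge name.  Used as worked-example input throughout.
SELECTED_EDGE_BETAS = {
    "Default A~Default C": 0.055810,
    "Default A~Limbic A": -0.014422,
    "Default B~Control C": -0.022168,
    "Default B~Salience A": 0.025213,
    "Default B~Visual A": 0.058361,
    "Default C~Dorsal Attention B": -0.027954,
    "Default C~Limbic A": 0.017076,
    "Default C~Somatomotor A": 0.008430,
}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def single_trace_history():
    """One item encoded once at t = 0 with first-trace decay d = φ = 0.3."""
    return encode(EncodingHistory("item"), 0.0, 0.3)


@pytest.fixture
def parcellation():
    return YEO17
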