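import pytest

from hvcphys import preset, simulate
from hvcphys.reproduce import feature_protocol, model_features


@pytest.fixture(scope="session")
def model_feats():
    """Feature battery of all six presets under the standard protocol."""
    return model_features()


@pytest.fixture(scope="session")
def adult_x_sweeps():
    """Adult HVC_X sweeps at -200, -10, +200 pA."""
    return simulate(preset("hvc_x@adult"), feature_protocol())


@pytest.fixture(scope="session")
def subsong_x_sweeps():
    return simulate(preset("hvc_x@subsong"), feature_protocol())
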