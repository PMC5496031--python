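import pytest

from rcdsim import load_parameters


@pytest.fixture(scope="session")
def params():
    """Default model parameters (calibrated k_out mode)."""
    return load_parameters()


@pytest.fixture(scope="session")
def params_table():
    """Model parameters with the printed (rounded) k_out = 0.19/day."""
    return load_parameters(k_out_mode="table")
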