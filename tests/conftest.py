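import pytest

from polysit import default_suzukii_parameters


@pytest.fixture(scope="session")
def params():
    """Table-2 style default parameter set (Last scenario refractory rates)."""
    return default_suzukii_parameters()


@pytest.fixture(scope="session")
def first_params(params):
    """First scenario: no effective multiple mating (tau_F = tau_I = 0)."""
    return params.replace(tau_F=0.0, tau_I=0.0)
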