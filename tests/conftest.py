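import pytest

from lifschemes import (
    NeuronParameters,
    NoiseParameters,
    euler_coefficients,
    exact_coefficients,
)


@pytest.fixture(scope="session")
def neuron():
    """Reference neuron: tau=10 ms, C=1 pF, theta=6 mV, reset 0 mV."""
    return NeuronParameters()


@pytest.fixture(scope="session")
def noise():
    """Reference drive: I ~ U[0, 1) pA switching every h=1 ms."""
    return NoiseParameters()


@pytest.fixture(scope="session")
def exact(neuron, noise):
    return exact_coefficients(neuron, noise.h)


@pytest.fixture(scope="session")
def euler(neuron, noise):
    return euler_coefficients(neuron, noise.h)
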