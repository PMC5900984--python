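import numpy as np
import pytest

from dwiphantom.protocol import Protocol, make_reference_protocols
from dwiphantom.signals import TwoCompartmentModel


@pytest.fixture(scope="session")
def protocols():
    """(adc_protocol, microstructure_protocol) reference pair."""
    return make_reference_protocols()


@pytest.fixture(scope="session")
def adc_protocol(protocols):
    return protocols[0]


@pytest.fixture(scope="session")
def micro_protocol(protocols):
    return protocols[1]


@pytest.fixture(scope="session")
def combined_protocol(protocols):
    adc, micro = protocols
    return Protocol(tuple(adc.measurements) + tuple(micro.measurements))


@pytest.fixture(scope="session")
def micro_model(micro_protocol):
    """Compiled two-compartment predictor bound to the microstructure protocol.

    Session-scoped so the JIT compilation cost is paid once.
    """
    model = TwoCompartmentModel(micro_protocol)
    model.predict(5.2, 0.35, 2.0)  # trigger compilation
    return model


@pytest.fixture(scope="session")
def clean_micro_signals(micro_model):
    """Noise-free normalized signals at the reference ground truth."""
    return micro_model.predict(5.2, 0.35, 2.0)


def master_seeds(n, master=0):
    """Shared convention for stochastic tests: seeds drawn from one master rng."""
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]
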