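import logging

import numpy as np
import pytest

from ripnet import build_network, default_parameters
from ripnet.network import KineticParameterSet, ReactionNetwork, Reaction, Species

logging.getLogger("ripnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def model2():
    return build_network("Model2")


@pytest.fixture(scope="session")
def model2_params():
    return default_parameters("Model2")


@pytest.fixture(scope="session")
def toy_binding_network():
    """A + B <-> C with large copy numbers (ODE is the SSA oracle)."""
    species = [Species("A", 5000), Species("B", 4000), Species("C", 0)]
    reactions = [
        Reaction("T1", "binding", (("A", 1), ("B", 1)), (("C", 1),), "kon"),
        Reaction("T2", "unbinding", (("C", 1),), (("A", 1), ("B", 1)), "koff"),
    ]
    return ReactionNetwork("toy", species, reactions)


@pytest.fixture(scope="session")
def toy_params():
    return KineticParameterSet({"kon": 2.0e-6, "koff": 5.0e-3})


@pytest.fixture(scope="session")
def minute_grid():
    return np.linspace(0.0, 420.0, 141)
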