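import numpy as np
import pytest

from cortexmodes import (
    ColumnNetwork,
    NeuronDynamicsParams,
    StimulusRegime,
    make_fixture_suite,
)


@pytest.fixture(scope="session")
def suite():
    return make_fixture_suite(0)


@pytest.fixture
def lif_params():
    return NeuronDynamicsParams(threshold=1.0, reset=0.0, rest=0.0,
                                leak_tau=5.0, refractory=1.0)


@pytest.fixture
def chain2():
    """A -> B, suprathreshold weight, delay 1.7."""
    return ColumnNetwork(
        n=2, sources=np.array([0]), targets=np.array([1]),
        weights=np.array([1.2]), delays=np.array([1.7]), seed=0, density=1.0,
    )


@pytest.fixture
def kick_A():
    return StimulusRegime(label="kick", spikes=[(0, 0.0)])
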