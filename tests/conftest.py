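import numpy as np
import pytest

from campnet.model_core import IntracellularParams, LightProtocol
from campnet.tissue import build_scenario, run_model_variant


@pytest.fixture(scope="session")
def params():
    return IntracellularParams()


@pytest.fixture(scope="session")
def one_pulse():
    """Single 40-min max-amplitude pulse after a 40-min dark lead-in."""
    return LightProtocol.two_pulse(amplitudes=(1.0,))


@pytest.fixture(scope="session")
def two_pulse():
    return LightProtocol.two_pulse()


@pytest.fixture(scope="session")
def single45():
    """One central emitter surrounded by 45 receivers."""
    return build_scenario("single_emitter_cluster", seed=0)


@pytest.fixture(scope="session")
def single10():
    return build_scenario("single_emitter_cluster", {"n_receivers": 10}, seed=0)


@pytest.fixture(scope="session")
def delayed_ts(single45, one_pulse):
    """Reference delayed-regulation run (tau_gj=15, N=4), shared."""
    return run_model_variant("delayed_regulation", graph=single45,
                             protocol=one_pulse)


def emitter_metrics(ts, pulse=0):
    from campnet.metrics import pulse_metrics_for_protocol

    e = int(np.flatnonzero(ts.roles == "emitter")[0])
    return pulse_metrics_for_protocol(
        ts.time, ts.ktr_nc[e], ts.metadata["protocol_pulses"]
    )[pulse]


def adjacent_receiver_metrics(ts, pulse=0):
    from campnet.metrics import pulse_metrics_for_protocol

    out = []
    for r in ts.graph.adjacent_receivers():
        out.append(
            pulse_metrics_for_protocol(
                ts.time, ts.ktr_nc[r], ts.metadata["protocol_pulses"]
            )[pulse]
        )
    return out
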