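import numpy as np
import pytest

from nichesync.agent import make_agent
from nichesync.blanket_coupling import EpochSchedule, couple, simulate_duet
from nichesync.generative_model import birdsong_model


@pytest.fixture(scope="session")
def model():
    return birdsong_model()


@pytest.fixture(scope="session")
def tick_model(model):
    return model.in_tick_units(1.0 / 256.0)


@pytest.fixture(scope="session")
def short_schedule():
    """Quarter-second epochs: enough structure for wiring/determinism tests."""
    return EpochSchedule(epoch_seconds=0.25, n_epochs=2)


@pytest.fixture(scope="session")
def short_duet_pair(model, short_schedule):
    """One short coupled and uncoupled run, shared across tests."""
    out = {}
    for mode in ("coupled", "uncoupled"):
        system = couple(make_agent(model), make_agent(model), mode,
                        short_schedule, model)
        out[mode] = (system, simulate_duet(system, seed=11))
    return out


@pytest.fixture(scope="session")
def full_duet_pair(model):
    """One full default duet pair (8 x 2 s epochs), shared across tests."""
    sched = EpochSchedule()
    out = {}
    for mode in ("coupled", "uncoupled"):
        system = couple(make_agent(model), make_agent(model), mode, sched, model)
        out[mode] = simulate_duet(system, seed=3)
    return out
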