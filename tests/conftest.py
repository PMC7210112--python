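import numpy as np
import pytest

from grcsim.cell import load_model, simulate_current_clamp, SUBTYPES


@pytest.fixture(scope="session")
def models():
    """The four calibrated reference subtype models."""
    return {tag: load_model(tag) for tag in SUBTYPES}


@pytest.fixture(scope="session")
def step_traces_10pa(models):
    """One 10 pA / 2 s current-clamp trace per subtype (shared; expensive)."""
    return {
        tag: simulate_current_clamp(m, 10.0, 2000.0) for tag, m in models.items()
    }


@pytest.fixture()
def synthetic_spike_trace():
    """A hand-built sawtooth trace with exactly three spikes."""
    from grcsim.cell import VoltageTrace

    dt = 0.1
    n = 5000
    v = np.full(n, -65.0)
    peaks = [1000, 2000, 3500]
    for p in peaks:
        v[p - 20 : p] = np.linspace(-65.0, 40.0, 20)
        v[p : p + 30] = np.linspace(40.0, -70.0, 30)
    return VoltageTrace(dt=dt, data={"soma": v}, stim={"onset_ms": 0.0}), np.array(peaks) * dt
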