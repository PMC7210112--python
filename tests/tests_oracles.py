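"""Independent closed-form oracles shared by the test modules."""

import math


def tm_steady_state(p: float, rate_hz: float, tau_rec: float, tau_facil: float) -> float:
    """Analytic fixed point of the Tsodyks-Markram recursion at a regular
    presynaptic rate: released fraction u+ * R- per pulse."""
    dt = 1e3 / rate_hz
    ef = math.exp(-dt / tau_facil)
    er = math.exp(-dt / tau_rec)
    u = p / (1.0 - ef * (1.0 - p))
    r = (1.0 - er) / (1.0 - (1.0 - u) * er)
    return u * r
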