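"""Experimental/simulation protocols run against a granule-cell model.

Three protocol families mirror the recordings:

* 2-s current steps from -65 mV (-8..22 pA in 2 pA increments);
* synaptic trains: 1 s of regular background stimulation (5-80 Hz)
  followed by a 250 ms burst at 100 Hz, repeated twice;
* the five-step depolarizing voltage-clamp protocol uncovering the
  depolarization-induced slow current (DISC), followed by a long
  observation window at the holding potential.

Protocols serialize to/from plain dicts (YAML-friendly) and round-trip
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Mapping

import numpy as np

from .cell import (
    DEFAULT_DT,
    GrCModel,
    VoltageTrace,
    simulate_current_clamp,
    simulate_voltage_clamp,
)
from .synapse import TMParameters, ReceptorSpec, build_drive

__all__ = [
    "CurrentStepProtocol",
    "SynapticTrainProtocol",
    "DISCProtocol",
    "run_current_steps",
    "run_synaptic_protocol",
    "run_disc_protocol",
    "SynapticResponse",
    "DISCMetrics",
]


@dataclass(frozen=True)
class CurrentStepProtocol:
    hold: float = -65.0
    amplitudes: tuple[float, ...] = tuple(range(-8, 24, 2))  # pA
    step_duration: float = 2000.0  # ms
    pre_ms: float = 200.0
    post_ms: float = 0.0

    def __post_init__(self):
        if list(self.amplitudes) != sorted(self.amplitudes):
            raise ValueError("amplitudes must be sorted")
        if self.step_duration < 0 or self.pre_ms < 0 or self.post_ms < 0:
            raise ValueError("durations must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amplitudes"] = list(self.amplitudes)
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "CurrentStepProtocol":
        d = dict(d)
        d["amplitudes"] = tuple(d.get("amplitudes", ()))
        return CurrentStepProtocol(**d)


@dataclass(frozen=True)
class SynapticTrainProtocol:
    background_rate: float = 20.0    # Hz, one of 5/10/20/40/60/80 in the assay
    background_duration: float = 1000.0  # ms
    burst_rate: float = 100.0        # Hz
    burst_duration: float = 250.0    # ms
    repeats: int = 2
    regularity: str = "regular"      # "regular" | "poisson"
    inter_repeat_ms: float = 1000.0  # recovery gap between repeats
    seed: int = 0                    # used by the poisson option only

    def __post_init__(self):
        if self.background_rate <= 0 or self.burst_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.regularity not in ("regular", "poisson"):
            raise ValueError("regularity must be 'regular' or 'poisson'")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: Mapping) -> "SynapticTrainProtocol":
        return SynapticTrainProtocol(**dict(d))

    def spike_times(self, repeat: int = 0) -> np.ndarray:
        """Presynaptic spike times (ms from repeat start)."""
        from .synth import generate_stimulus_train

        bg = generate_stimulus_train(
            self.background_rate,
            self.background_duration,
            mode=self.regularity,
            seed=self.seed + repeat,
        )
        burst = generate_stimulus_train(
            self.burst_rate, self.burst_duration, mode="regular"
        )
        return np.concatenate([bg, burst + self.background_duration])


@dataclass(frozen=True)
class DISCProtocol:
    """Five depolarizing voltage-clamp steps, then a long observation window.

    The experimental step values are not published for this cell type; the
    defaults (5 x 100 ms steps from -65 to 0 mV at 2 Hz) follow the
    Purkinje-cell protocol family and are fully configurable.
    """

    n_steps: int = 5
    hold: float = -65.0
    step_amplitude: float = 0.0      # command level during a step (mV)
    step_duration: float = 100.0     # ms
    interstep_duration: float = 400.0  # ms -> 2 Hz step rate
    post_observation: float = 4000.0  # ms

    def __post_init__(self):
        if self.n_steps != 5:
            raise ValueError("the DISC protocol uses exactly five steps")
        if self.post_observation < 4000.0:
            raise ValueError("post_observation must be >= 4000 ms")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: Mapping) -> "DISCProtocol":
        return DISCProtocol(**dict(d))

    def command(self) -> list[tuple[float, float]]:
        segs: list[tuple[float, float]] = [(200.0, self.hold)]
        for _ in range(self.n_steps):
            segs.append((self.step_duration, self.step_amplitude))
            segs.append((self.interstep_duration, self.hold))
        segs[-1] = (self.post_observation, self.hold)
        return segs

    @property
    def train_end_ms(self) -> float:
        """Time of the end of the last depolarizing step (ms from start)."""
        return 200.0 + self.n_steps * self.step_duration + (
            self.n_steps - 1
        ) * self.interstep_duration


# ---------------------------------------------------------------------------


def run_current_steps(
    model: GrCModel,
    proto: CurrentStepProtocol | None = None,
    dt: float = DEFAULT_DT,
    record=("soma",),
) -> dict[float, VoltageTrace]:
    """One current-clamp trace per step amplitude."""
    proto = proto or CurrentStepProtocol()
    return {
        amp: simulate_current_clamp(
            model,
            amp,
            proto.step_duration,
            hold=proto.hold,
            dt=dt,
            pre_ms=proto.pre_ms,
            post_ms=proto.post_ms,
            record=record,
        )
        for amp in proto.amplitudes
    }


@dataclass(frozen=True)
class SynapticResponse:
    trace: VoltageTrace
    f_resp_background: float   # Hz, steady-state half of the background phase
    f_resp_burst: float        # Hz over the burst window
    f_stim_background: float
    f_stim_burst: float
    per_repeat: tuple = ()


def run_synaptic_protocol(
    model: GrCModel,
    synapse: TMParameters,
    proto: SynapticTrainProtocol | None = None,
    receptor: ReceptorSpec | None = None,
    dt: float = DEFAULT_DT,
    hold: float = -65.0,
) -> SynapticResponse:
    """Background + burst mossy-fiber stimulation of a model.

    Response rates are measured over the last half of the background phase
    (steady state) and over the full burst window, averaged across repeats.
    """
    from .features import detect_spikes, window_rate

    proto = proto or SynapticTrainProtocol()
    pre = 200.0
    repeat_len = proto.background_duration + proto.burst_duration
    bg_rates, burst_rates, traces = [], [], []
    for rep in range(proto.repeats):
        st = proto.spike_times(repeat=rep)
        n_steps = int(round((pre + repeat_len + 100.0) / dt))
        drive = build_drive(
            synapse, st, n_steps, dt, receptor=receptor, offset_ms=pre
        )
        trace = simulate_current_clamp(
            model,
            0.0,
            repeat_len + 100.0,
            hold=hold,
            dt=dt,
            pre_ms=pre,
            syn=drive,
        )
        spikes = detect_spikes(trace)
        bg_rates.append(
            window_rate(
                spikes, proto.background_duration / 2.0, proto.background_duration
            )
        )
        burst_rates.append(
            window_rate(
                spikes,
                proto.background_duration,
                proto.background_duration + proto.burst_duration,
            )
        )
        traces.append(trace)
    return SynapticResponse(
        trace=traces[0],
        f_resp_background=float(np.mean(bg_rates)),
        f_resp_burst=float(np.mean(burst_rates)),
        f_stim_background=proto.background_rate,
        f_stim_burst=proto.burst_rate,
        per_repeat=tuple(zip(bg_rates, burst_rates)),
    )


@dataclass(frozen=True)
class DISCMetrics:
    onset_latency_ms: float | None   # from the end of the step train
    charge_transfer_pa_ms: float     # integral of the inward deviation (<= 0)
    trace: VoltageTrace | None = None


def disc_metrics_from_current(
    i_pa: np.ndarray,
    dt: float,
    train_end_ms: float,
    window_ms: float = 2000.0,
    noise_sd_mult: float = 3.0,
    min_sustain_ms: float = 20.0,
) -> DISCMetrics:
    """Extract DISC onset latency and charge transfer from a clamp-current
    trace.

    The baseline and its noise band are taken from the 200 ms immediately
    preceding the step train's first step; onset is the first deviation
    below (inward) baseline - noise_sd_mult*SD sustained for
    ``min_sustain_ms``; charge is the integral of the inward deviation over
    ``window_ms`` after the train.
    """
    i0 = int(round(train_end_ms / dt))
    base_seg = i_pa[: int(round(150.0 / dt))]
    base = float(np.median(base_seg))
    sd = float(np.std(base_seg))
    # skip the capacitive/tail settling right after the last step
    skip = int(round(50.0 / dt))
    seg = i_pa[i0 + skip : i0 + int(round(window_ms / dt))]
    dev = seg - base
    thresh = -max(noise_sd_mult * sd, 0.15)
    below = dev < thresh
    need = int(round(min_sustain_ms / dt))
    onset = None
    run = 0
    for k, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= need:
            onset = (k - need + 1 + skip) * dt
            break
    charge = float(np.sum(np.minimum(dev, 0.0)) * dt)
    return DISCMetrics(onset_latency_ms=onset, charge_transfer_pa_ms=charge)


def run_disc_protocol(
    model: GrCModel,
    proto: DISCProtocol | None = None,
    dt: float = DEFAULT_DT,
) -> DISCMetrics:
    """Run the five-step voltage-clamp protocol and extract DISC metrics."""
    proto = proto or DISCProtocol()
    trace = simulate_voltage_clamp(model, proto.command(), dt=dt)
    m = disc_metrics_from_current(
        np.asarray(trace["clamp_current"]), dt, proto.train_end_ms
    )
    return DISCMetrics(
        onset_latency_ms=m.onset_latency_ms,
        charge_transfer_pa_ms=m.charge_transfer_pa_ms,
        trace=trace,
    )
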