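"""Voltage-gated channel models for the granule-cell conductance complement.

Each channel is described by Hodgkin-Huxley-style gates.  A gate has a
Boltzmann steady state

    x_inf(V) = floor + (1 - floor) / (1 + exp(-(V - vhalf)/slope))

(``slope`` < 0 for inactivation gates, ``floor`` > 0 for incomplete
inactivation, e.g. the FHF-modulated Nav1.6 variant with a persistent
component) and a bell-shaped voltage-dependent time constant

    tau(V) = tau_min + tau_amp / (exp((V - tau_vhalf)/tau_s1)
                                  + exp(-(V - tau_vhalf)/tau_s2))   [ms]

Q10-corrected to the simulation temperature.  Channel parameters are data,
not code: they live in ``data/channels.yaml`` together with the
compartment distribution table and the conductance-density bounds used by
the optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "ChannelTable",
    "gate_steady_state",
    "gate_time_constant",
    "channel_current",
    "q10_scale",
    "load_channel_table",
]

#: canonical channel names of the granule-cell complement
CHANNEL_NAMES = (
    "Nav1.6",
    "Nav1.6+FHF",
    "Kv1.1",
    "Kv1.5",
    "Kv2",
    "Kv4.3",
    "Kv3.4",
    "Kv7",
    "Cav2.2",
    "KCa1.1",
    "TRPM4",
    "leak",
)

#: default simulation temperature (deg C); kinetics are Q10-corrected to it
SIM_TEMPERATURE = 32.0


class ConfigurationError(ValueError):
    """Raised when a channel table or model configuration is inconsistent."""


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gate (activation or inactivation particle)."""

    name: str
    exponent: int = 1
    vhalf: float = -40.0          # mV
    slope: float = 6.0            # mV; negative for inactivation
    floor: float = 0.0            # residual open fraction (persistent current)
    tau_min: float = 0.1          # ms
    tau_amp: float = 0.0          # ms
    tau_vhalf: float = -40.0      # mV
    tau_s1: float = 15.0          # mV
    tau_s2: float = 15.0          # mV
    q10: float = 3.0
    t_ref: float = 23.0           # deg C at which tau_* were measured

    def steady_state(self, v: float) -> float:
        return gate_steady_state(self, v)

    def time_constant(self, v: float, t_sim: float = SIM_TEMPERATURE) -> float:
        return q10_scale(gate_time_constant(self, v), t_sim, self)


@dataclass(frozen=True)
class ChannelSpec:
    """A channel population in one (or several) compartments.

    ``gmax`` is a conductance density in mS/cm^2; ``reversal`` in mV.
    Calcium- or CaM2C-gated channels (KCa1.1, TRPM4) carry ``kind`` tags and
    ligand parameters instead of voltage gates.
    """

    name: str
    reversal: float
    gmax: float
    gates: tuple[GateSpec, ...] = ()
    compartments: frozenset[str] = frozenset()
    kind: str = "hh"              # "hh" | "ca_gated" | "cam_gated" | "leak"
    feeds_ca_shell: bool = False  # Cav2.2 current drives the Ca shell
    ligand_kd: float = 0.0        # half-activation [nM] for ligand-gated kinds
    ligand_hill: float = 1.0

    def __post_init__(self):
        if self.gmax < 0:
            raise ConfigurationError(f"{self.name}: gmax must be >= 0")


def gate_steady_state(gate: GateSpec, v: float) -> float:
    """Steady-state open fraction of ``gate`` at membrane potential ``v`` (mV)."""
    if not math.isfinite(v):
        raise ValueError("membrane potential must be finite")
    x = 1.0 / (1.0 + math.exp(-(v - gate.vhalf) / gate.slope))
    return gate.floor + (1.0 - gate.floor) * x


def gate_time_constant(gate: GateSpec, v: float) -> float:
    """Voltage-dependent time constant (ms) at the reference temperature."""
    bell = math.exp((v - gate.tau_vhalf) / gate.tau_s1) + math.exp(
        -(v - gate.tau_vhalf) / gate.tau_s2
    )
    return gate.tau_min + gate.tau_amp / bell


def q10_scale(tau_ref: float, t_sim: float, gate: GateSpec) -> float:
    """Scale a time constant from the gate's reference temperature to ``t_sim``."""
    if gate.q10 <= 0:
        raise ConfigurationError(f"gate {gate.name}: q10 must be > 0")
    return tau_ref / gate.q10 ** ((t_sim - gate.t_ref) / 10.0)


def channel_current(
    chan: ChannelSpec, v: float, gate_values: Mapping[str, float]
) -> float:
    """Ohmic channel current density, outward positive (mA/cm^2).

    I = gmax * prod(gate^exponent) * (V - E); gmax in mS/cm^2, V in mV gives
    uA/cm^2, converted to mA/cm^2.
    """
    open_frac = 1.0
    for g in chan.gates:
        try:
            x = gate_values[g.name]
        except KeyError:
            raise ConfigurationError(
                f"channel {chan.name}: missing value for gate {g.name!r}"
            ) from None
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"gate {g.name} value {x} outside [0, 1]")
        open_frac *= x**g.exponent
    # mS/cm^2 * mV = uA/cm^2 -> mA/cm^2
    return chan.gmax * open_frac * (v - chan.reversal) * 1e-3


# ---------------------------------------------------------------------------
# channel table (single source of truth for kinetics, distribution, bounds)
# ---------------------------------------------------------------------------

@dataclass
class ChannelTable:
    """Parsed channel table: kinetics + per-compartment densities and bounds."""

    channels: dict[str, dict] = field(default_factory=dict)

    def gate_specs(self, name: str) -> tuple[GateSpec, ...]:
        entry = self.channels[name]
        return tuple(
            GateSpec(
                name=g["name"],
                exponent=int(g.get("exponent", 1)),
                vhalf=float(g.get("vhalf", -40.0)),
                slope=float(g.get("slope", 6.0)),
                floor=float(g.get("floor", 0.0)),
                tau_min=float(g.get("tau_min", 0.1)),
                tau_amp=float(g.get("tau_amp", 0.0)),
                tau_vhalf=float(g.get("tau_vhalf", g.get("vhalf", -40.0))),
                tau_s1=float(g.get("tau_s1", 15.0)),
                tau_s2=float(g.get("tau_s2", 15.0)),
                q10=float(g.get("q10", 3.0)),
                t_ref=float(g.get("t_ref", 23.0)),
            )
            for g in entry.get("gates", ())
        )

    def build(self, name: str, compartment: str, gmax: float | None = None) -> ChannelSpec:
        """Instantiate ``ChannelSpec`` for one compartment.

        ``gmax`` overrides the table default (used by the optimizer); it must
        stay inside the configured bounds.
        """
        entry = self.channels[name]
        dist = entry.get("distribution", {})
        if compartment not in dist:
            raise ConfigurationError(
                f"channel {name} is not configured for compartment {compartment}"
            )
        default = float(dist[compartment]["gmax"])
        lo, hi = self.bounds(name, compartment)
        g = default if gmax is None else float(gmax)
        if not lo <= g <= hi:
            raise ConfigurationError(
                f"{name}@{compartment}: gmax {g} outside bounds [{lo}, {hi}]"
            )
        return ChannelSpec(
            name=name,
            reversal=float(entry["reversal"]),
            gmax=g,
            gates=self.gate_specs(name),
            compartments=frozenset(dist),
            kind=entry.get("kind", "hh"),
            feeds_ca_shell=bool(entry.get("feeds_ca_shell", False)),
            ligand_kd=float(entry.get("ligand_kd", 0.0)),
            ligand_hill=float(entry.get("ligand_hill", 1.0)),
        )

    def bounds(self, name: str, compartment: str) -> tuple[float, float]:
        d = self.channels[name]["distribution"][compartment]
        b = d.get("bounds")
        if b is None:
            g = float(d["gmax"])
            return (0.0, max(4.0 * g, 1e-9))
        return (float(b[0]), float(b[1]))

    def compartments_of(self, name: str) -> frozenset[str]:
        return frozenset(self.channels[name].get("distribution", {}))

    def validate(self) -> None:
        for name, entry in self.channels.items():
            if "reversal" not in entry:
                raise ConfigurationError(f"channel {name}: missing reversal")
            if not entry.get("distribution"):
                raise ConfigurationError(f"channel {name}: empty distribution")
            for comp, d in entry["distribution"].items():
                if float(d["gmax"]) < 0:
                    raise ConfigurationError(f"{name}@{comp}: negative gmax")
                lo, hi = self.bounds(name, comp)
                if not lo <= float(d["gmax"]) <= hi:
                    raise ConfigurationError(
                        f"{name}@{comp}: default gmax outside its bounds"
                    )
            for g in self.gate_specs(name):
                if g.q10 <= 0:
                    raise ConfigurationError(f"{name}/{g.name}: q10 <= 0")
                for v in (-100.0, -65.0, -40.0, 0.0, 60.0):
                    x = gate_steady_state(g, v)
                    if not 0.0 <= x <= 1.0 + 1e-12:
                        raise ConfigurationError(
                            f"{name}/{g.name}: steady state {x} outside [0,1]"
                        )
                    if g.time_constant(v) <= 0:
                        raise ConfigurationError(f"{name}/{g.name}: tau <= 0")


def load_channel_table(path: str | None = None) -> ChannelTable:
    """Load and validate the channel table (default: packaged ``channels.yaml``)."""
    if path is None:
        text = (
            resources.files("grcsim").joinpath("data/channels.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    table = ChannelTable(channels=raw["channels"])
    table.validate()
    return table
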