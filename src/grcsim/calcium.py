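"""Submembrane Ca2+ dynamics, cooperative Ca2+-Calmodulin binding and the
CaM2C-gated TRPM4 current.

The mechanism producing delayed firing acceleration is a chain:

  Cav2.2 current -> submembrane Ca2+ shell (Calretinin-buffered, extruded
  toward ~100 nM rest) -> cooperative (second-order in Ca2+) binding to
  Calmodulin forming the two-Ca C-lobe complex CaM2C -> once CaM2C crosses
  a concentration threshold, a steep Hill function opens TRPM4, a
  Ca-impermeable nonselective cation channel (E_rev = 0 mV) whose inward
  current at sub-threshold potentials depolarizes the cell and accelerates
  firing.  The threshold crossing takes seconds, which is what delays the
  acceleration relative to discharge onset.

The shell is a single well-mixed compartment (no radial diffusion): the
relevant behaviour is a slow threshold crossing, not a spatial profile.
All concentrations are in nM, time in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "CalciumShell",
    "CalmodulinState",
    "TRPM4State",
    "step_calcium",
    "step_cam2c",
    "trpm4_open_inf",
    "trpm4_current",
    "influx_factor",
]

FARADAY = 96485.332  # C/mol


@dataclass(frozen=True)
class CalciumShell:
    """Well-mixed submembrane shell with a single-site fast buffer."""

    ca_free: float = 100.0        # nM
    ca_rest: float = 100.0        # nM
    shell_depth: float = 0.3      # um
    area: float = 105.7           # um^2 of membrane backing the shell
    extrusion_rate: float = 0.05  # 1/ms, pump linearized around rest
    buffer_bound: float = 0.0     # nM
    buffer_total: float = 10000.0  # nM  (Calretinin-like single site)
    buffer_kon: float = 1.0e-5    # 1/(nM*ms)
    buffer_koff: float = 0.005    # 1/ms

    def __post_init__(self):
        if self.ca_free < 0 or self.buffer_bound < 0:
            raise ValueError("concentrations must be non-negative")
        if self.buffer_bound > self.buffer_total:
            raise ValueError("buffer_bound exceeds buffer_total")


@dataclass(frozen=True)
class CalmodulinState:
    """Free CaM and its two-Ca C-lobe complex; total CaM is conserved."""

    cam_total: float = 10000.0    # nM
    cam2c: float = 0.0            # nM
    kon2: float = 2.0e-11         # 1/(nM^2 * ms), cooperative forward rate
    koff2: float = 1.0e-4         # 1/ms

    @property
    def cam_free(self) -> float:
        return self.cam_total - self.cam2c


@dataclass(frozen=True)
class TRPM4State:
    """CaM2C-gated TRPM4 conductance state (Ca-impermeable, E_rev = 0 mV)."""

    g_max: float = 0.0            # mS/cm^2
    open_fraction: float = 0.0
    cam2c_threshold: float = 40.0  # nM, half-activation of the Hill gate
    hill_n: float = 10.0
    act_tau: float = 300.0        # ms
    deact_tau: float = 1000.0     # ms
    reversal: float = 0.0         # mV, fixed near 0


def influx_factor(area_um2: float, shell_depth_um: float) -> float:
    """nM of shell Ca2+ per (pA * ms) of inward Ca2+ current.

    Shell volume = area * depth; 1 pA for 1 ms delivers 1e-15 C, i.e.
    1e-15/(2 F) mol of Ca2+.
    """
    vol_l = area_um2 * shell_depth_um * 1e-15  # um^3 -> litres (1 um^3 = 1e-15 l)
    mol_per_pa_ms = 1e-15 / (2.0 * FARADAY)
    return mol_per_pa_ms / vol_l * 1e9  # -> nM


def step_calcium(shell: CalciumShell, i_ca: float, dt: float) -> CalciumShell:
    """Advance the shell by ``dt`` ms under Ca2+ current ``i_ca`` (pA, inward
    negative following the electrophysiological sign convention).

    Forward-Euler mass action; a ``dt`` large enough to drive any
    concentration negative is rejected rather than clipped.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    influx = -i_ca * influx_factor(shell.area, shell.shell_depth)  # nM/ms
    free_buf = shell.buffer_total - shell.buffer_bound
    bind = shell.buffer_kon * shell.ca_free * free_buf - shell.buffer_koff * shell.buffer_bound
    dca = influx - shell.extrusion_rate * (shell.ca_free - shell.ca_rest) - bind
    ca = shell.ca_free + dt * dca
    bound = shell.buffer_bound + dt * bind
    if ca < 0 or bound < 0 or bound > shell.buffer_total:
        raise ValueError(
            f"dt={dt} ms drives the Ca shell out of range (ca={ca:.3g} nM, "
            f"bound={bound:.3g} nM); reduce the step"
        )
    return replace(shell, ca_free=ca, buffer_bound=bound)


def step_cam2c(cam: CalmodulinState, ca_free: float, dt: float) -> CalmodulinState:
    """Mass-action CaM2C update with a cooperative (ca^2) forward rate."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    fwd = cam.kon2 * ca_free * ca_free * cam.cam_free
    back = cam.koff2 * cam.cam2c
    cam2c = cam.cam2c + dt * (fwd - back)
    if cam2c < 0 or cam2c > cam.cam_total:
        raise ValueError(f"dt={dt} ms drives CaM2C out of [0, total]")
    return replace(cam, cam2c=cam2c)


def trpm4_open_inf(state: TRPM4State, cam2c: float) -> float:
    """Steady-state open fraction: Hill function of CaM2C."""
    if cam2c <= 0.0:
        return 0.0
    x = (cam2c / state.cam2c_threshold) ** state.hill_n
    return x / (1.0 + x)


def trpm4_current(
    state: TRPM4State, cam2c: float, v: float, dt: float, area_um2: float = 105.7
) -> tuple[TRPM4State, float]:
    """Relax the open fraction toward its Hill target and return (state, I).

    Current is returned in pA for a membrane patch of ``area_um2``
    (outward positive); the channel is Ca-impermeable so it feeds nothing
    back into the Ca shell.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    target = trpm4_open_inf(state, cam2c)
    tau = state.act_tau if target > state.open_fraction else state.deact_tau
    o = target + (state.open_fraction - target) * math.exp(-dt / tau)
    # mS/cm^2 * um^2 = 1e-8 mS = 1e-5 uS; uS*mV = nA -> pA: *1e3
    g_pa_per_mv = state.g_max * area_um2 * 1e-8 * 1e3
    i = g_pa_per_mv * o * (v - state.reversal)
    return replace(state, open_fraction=o), i
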