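"""Multi-compartment granule-cell model: construction, simulation, validation.

The cell is a tree of ten compartments (soma, four dendrites, hillock, AIS,
ascending axon, two parallel-fiber branches).  Channels are instantiated
per compartment from the channel table; the soma carries the Ca2+ shell,
the CaM2C reaction and the TRPM4 conductance.  Simulations use a fixed-step
implicit integrator (Crank-Nicolson by default) with a Hines tree solve;
see :mod:`grcsim._kernel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from . import _kernel
from .calcium import influx_factor
from .channels import (
    ChannelSpec,
    ChannelTable,
    ConfigurationError,
    SIM_TEMPERATURE,
    load_channel_table,
)

__all__ = [
    "COMPARTMENTS",
    "Compartment",
    "GrCModel",
    "VoltageTrace",
    "SynapticDrive",
    "IntegrationError",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "validate_model",
    "load_model",
    "SUBTYPES",
]

#: tree order: every parent precedes its children
COMPARTMENTS = (
    "soma",
    "dendrite_1",
    "dendrite_2",
    "dendrite_3",
    "dendrite_4",
    "hillock",
    "AIS",
    "AA",
    "PF_left",
    "PF_right",
)

SUBTYPES = ("strong_adapting", "mild_adapting", "non_adapting", "accelerating")

DEFAULT_DT = 0.005  # ms; count-stable under step halving for all reference models


class IntegrationError(RuntimeError):
    """Numerical failure during integration (blow-up or negative Ca)."""


@dataclass(frozen=True)
class Compartment:
    label: str
    parent: str | None
    length: float            # um
    diameter: float          # um
    axial_resistivity: float = 100.0  # Ohm*cm
    cm: float = 1.0          # uF/cm^2

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ConfigurationError(f"{self.label}: geometry must be positive")

    @property
    def area_um2(self) -> float:
        return math.pi * self.diameter * self.length

    @property
    def area_cm2(self) -> float:
        return self.area_um2 * 1e-8

    @property
    def cross_section_cm2(self) -> float:
        return math.pi * (self.diameter * 1e-4) ** 2 / 4.0


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled voltages (mV) or clamp current (pA) per location."""

    dt: float
    data: Mapping[str, np.ndarray]
    stim: Mapping[str, object] = field(default_factory=dict)
    aux: Mapping[str, np.ndarray] = field(default_factory=dict)
    unit: str = "mV"

    def __post_init__(self):
        for k, v in self.data.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite samples in trace {k!r}")

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(self.data)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.data.values())))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def onset(self) -> float:
        """Stimulus onset (ms from trace start); 0 when unannotated."""
        return float(self.stim.get("onset_ms", 0.0))

    def __getitem__(self, loc: str) -> np.ndarray:
        return self.data[loc]


@dataclass(frozen=True)
class SynapticDrive:
    """Precomputed synaptic conductance time series for the integrator.

    ``g_ampa``/``g_nmda`` are (n_steps, n_sites) arrays in uS aligned to the
    simulation grid; ``sites`` are compartment labels (dendrites).
    """

    sites: tuple[str, ...]
    g_ampa: np.ndarray
    g_nmda: np.ndarray


@dataclass(frozen=True)
class GrCModel:
    """A fully simulatable granule-cell model."""

    compartments: tuple[Compartment, ...]
    table: ChannelTable
    gmax_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)
    trpm4_enabled: bool = True
    subtype_tag: str | None = None
    calcium: Mapping[str, float] = field(default_factory=dict)
    calmodulin: Mapping[str, float] = field(default_factory=dict)
    trpm4: Mapping[str, float] = field(default_factory=dict)
    temperature: float = SIM_TEMPERATURE

    # ------------------------------------------------------------------ build
    @staticmethod
    def from_config(
        subtype: str | None = None,
        model_config: str | None = None,
        channel_table: ChannelTable | None = None,
        gmax_overrides: Mapping[tuple[str, str], float] | None = None,
        trpm4_enabled: bool | None = None,
    ) -> "GrCModel":
        cfg = _load_yaml(model_config, "data/model.yaml")
        table = channel_table or load_channel_table()
        morph = cfg["morphology"]
        passive = cfg.get("passive", {})
        comps = []
        for label in COMPARTMENTS:
            m = morph[label]
            comps.append(
                Compartment(
                    label=label,
                    parent=m.get("parent"),
                    length=float(m["length"]),
                    diameter=float(m["diameter"]),
                    axial_resistivity=float(passive.get("axial_resistivity", 100.0)),
                    cm=float(passive.get("cm", 1.0)),
                )
            )
        overrides: dict[tuple[str, str], float] = {}
        tag = None
        trpm4_on = True
        if subtype is not None:
            sub = _load_yaml(None, f"data/subtypes/{subtype}.yaml")
            tag = sub.get("tag", subtype)
            trpm4_on = bool(sub.get("trpm4_enabled", False))
            for chan, per_comp in sub.get("gmax", {}).items():
                for comp, val in per_comp.items():
                    overrides[(chan, comp)] = float(val)
        if gmax_overrides:
            overrides.update(gmax_overrides)
        if trpm4_enabled is not None:
            trpm4_on = trpm4_enabled
        model = GrCModel(
            compartments=tuple(comps),
            table=table,
            gmax_overrides=overrides,
            trpm4_enabled=trpm4_on,
            subtype_tag=tag,
            calcium=cfg.get("calcium", {}),
            calmodulin=cfg.get("calmodulin", {}),
            trpm4=cfg.get("trpm4", {}),
        )
        model._check_tree()
        return model

    def with_gmax(self, updates: Mapping[tuple[str, str], float]) -> "GrCModel":
        new = dict(self.gmax_overrides)
        new.update(updates)
        return replace(self, gmax_overrides=new)

    def _check_tree(self) -> None:
        idx = {c.label: i for i, c in enumerate(self.compartments)}
        if self.compartments[0].parent is not None:
            raise ConfigurationError("tree must be rooted at soma")
        for c in self.compartments[1:]:
            if c.parent not in idx or idx[c.parent] >= idx[c.label]:
                raise ConfigurationError(
                    f"{c.label}: parent must precede it in the tree order"
                )

    # ------------------------------------------------------------- properties
    @property
    def comp_index(self) -> dict[str, int]:
        return {c.label: i for i, c in enumerate(self.compartments)}

    @property
    def total_capacitance_pf(self) -> float:
        return sum(c.cm * c.area_cm2 for c in self.compartments) * 1e6

    def channels_in(self, label: str) -> list[ChannelSpec]:
        out = []
        for name in self.table.channels:
            if label in self.table.compartments_of(name):
                g = self.gmax_overrides.get((name, label))
                spec = self.table.build(name, label, g)
                if name == "TRPM4" and not self.trpm4_enabled:
                    spec = replace(spec, gmax=0.0)
                out.append(spec)
        return out

    @property
    def gmax_vector(self) -> dict[tuple[str, str], float]:
        vec = {}
        for comp in self.compartments:
            for spec in self.channels_in(comp.label):
                vec[(spec.name, comp.label)] = spec.gmax
        return vec

    # ---------------------------------------------------------------- packing
    def packed(self) -> dict:
        """Pack the model into the flat arrays the kernel consumes."""
        idx = self.comp_index
        ncomp = len(self.compartments)
        parent = np.full(ncomp, -1, dtype=np.int64)
        g_ax = np.zeros(ncomp)
        cap = np.zeros(ncomp)
        for i, c in enumerate(self.compartments):
            cap[i] = c.cm * c.area_cm2 * 1e3  # uF -> nF
            if c.parent is not None:
                p = self.compartments[idx[c.parent]]
                parent[i] = idx[c.parent]
                r_ohm = (
                    c.axial_resistivity * (c.length * 1e-4 / 2.0) / c.cross_section_cm2
                    + p.axial_resistivity * (p.length * 1e-4 / 2.0) / p.cross_section_cm2
                )
                g_ax[i] = 1e6 / r_ohm  # uS

        ch_comp, ch_g, ch_E, ch_kind, ch_gstart, ch_ng = [], [], [], [], [], []
        ch_kd, ch_hill, ch_feeds = [], [], []
        gp_rows, gate_comp = [], []
        kind_code = {
            "hh": _kernel.KIND_HH,
            "ca_gated": _kernel.KIND_CA_GATED,
            "cam_gated": _kernel.KIND_CAM_GATED,
            "leak": _kernel.KIND_LEAK,
        }
        qexp = lambda g: g.q10 ** ((self.temperature - g.t_ref) / 10.0)
        for i, c in enumerate(self.compartments):
            for spec in self.channels_in(c.label):
                ch_comp.append(i)
                ch_g.append(spec.gmax * c.area_cm2 * 1e3)  # mS -> uS
                ch_E.append(spec.reversal)
                ch_kind.append(kind_code[spec.kind])
                ch_gstart.append(len(gp_rows))
                ch_ng.append(len(spec.gates) if spec.kind == "hh" else 0)
                ch_kd.append(spec.ligand_kd if spec.ligand_kd > 0 else 1.0)
                ch_hill.append(spec.ligand_hill)
                ch_feeds.append(1 if spec.feeds_ca_shell else 0)
                if spec.kind == "hh":
                    for g in spec.gates:
                        q = qexp(g)
                        gp_rows.append(
                            [
                                g.vhalf,
                                g.slope,
                                g.floor,
                                g.tau_min / q,
                                g.tau_amp / q,
                                g.tau_vhalf,
                                g.tau_s1,
                                g.tau_s2,
                                float(g.exponent),
                            ]
                        )
                        gate_comp.append(i)

        soma = self.compartments[0]
        cal = dict(self.calcium)
        cam = dict(self.calmodulin)
        trp = dict(self.trpm4)
        ca_par = np.array(
            [
                influx_factor(soma.area_um2, float(cal.get("shell_depth", 0.1))),
                float(cal.get("extrusion_rate", 0.02)),
                float(cal.get("ca_rest", 100.0)),
                float(cal.get("buffer_kon", 1e-5)),
                float(cal.get("buffer_koff", 0.01)),
                float(cal.get("buffer_total", 1500.0)),
                float(cam.get("kon2", 1.2e-11)),
                float(cam.get("koff2", 1e-4)),
                float(cam.get("cam_total", 10000.0)),
                float(trp.get("cam2c_threshold", 50.0)),
                float(trp.get("hill_n", 6.0)),
                float(trp.get("act_tau", 50.0)),
                float(trp.get("deact_tau", 300.0)),
                soma.area_um2,
                float(trp.get("kca_tau", 1000.0)),
            ]
        )
        return {
            "parent": parent,
            "g_ax": g_ax,
            "cap": cap,
            "ch_comp": np.array(ch_comp, dtype=np.int64),
            "ch_g": np.array(ch_g, dtype=float),
            "ch_E": np.array(ch_E, dtype=float),
            "ch_kind": np.array(ch_kind, dtype=np.int64),
            "ch_gstart": np.array(ch_gstart, dtype=np.int64),
            "ch_ng": np.array(ch_ng, dtype=np.int64),
            "ch_kd": np.array(ch_kd, dtype=float),
            "ch_hill": np.array(ch_hill, dtype=float),
            "ch_feeds": np.array(ch_feeds, dtype=np.int64),
            "gp": np.array(gp_rows, dtype=float).reshape(len(gp_rows), 9),
            "gate_comp": np.array(gate_comp, dtype=np.int64),
            "ca_par": ca_par,
        }


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------

def _gate_steady_states(packed: dict, v: float) -> np.ndarray:
    gp = packed["gp"]
    if gp.size == 0:
        return np.zeros(0)
    minf = gp[:, _kernel.GP_FLOOR] + (1.0 - gp[:, _kernel.GP_FLOOR]) / (
        1.0 + np.exp(-(v - gp[:, _kernel.GP_VHALF]) / gp[:, _kernel.GP_SLOPE])
    )
    return minf


def _run(
    model: GrCModel,
    mode: int,
    n_steps: int,
    dt: float,
    i_inj: np.ndarray | None = None,
    vcmd: np.ndarray | None = None,
    v_init: float = -65.0,
    syn: SynapticDrive | None = None,
    theta: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    p = model.packed()
    ncomp = len(model.compartments)
    v0 = np.full(ncomp, v_init, dtype=float)
    m0 = _gate_steady_states(p, v_init)
    ca_rest = p["ca_par"][2]
    b_kon, b_koff, b_tot = p["ca_par"][3], p["ca_par"][4], p["ca_par"][5]
    bound0 = b_kon * ca_rest * b_tot / (b_kon * ca_rest + b_koff)
    kca_kd = kca_hill = None
    for c in range(len(p["ch_comp"])):
        if p["ch_kind"][c] == _kernel.KIND_CA_GATED:
            kca_kd, kca_hill = p["ch_kd"][c], p["ch_hill"][c]
            break
    if kca_kd is not None:
        x = (ca_rest / kca_kd) ** kca_hill
        o_kca0 = x / (1.0 + x)
    else:
        o_kca0 = 0.0
    state0 = np.array([ca_rest, bound0, 0.0, 0.0, o_kca0])
    if i_inj is None:
        i_inj = np.zeros(n_steps)
    if vcmd is None:
        vcmd = np.full(n_steps, v_init)
    if syn is None:
        syn_comp = np.zeros(0, dtype=np.int64)
        g_ampa = np.zeros((n_steps, 0))
        g_nmda = np.zeros((n_steps, 0))
    else:
        idx = model.comp_index
        syn_comp = np.array([idx[s] for s in syn.sites], dtype=np.int64)
        g_ampa = np.ascontiguousarray(syn.g_ampa, dtype=float)
        g_nmda = np.ascontiguousarray(syn.g_nmda, dtype=float)
        if g_ampa.shape != (n_steps, len(syn.sites)):
            raise ValueError("synaptic drive not aligned with the simulation grid")
    v_out, aux, status, comp = _kernel.integrate(
        dt,
        n_steps,
        theta,
        p["parent"],
        p["g_ax"],
        p["cap"],
        p["ch_comp"],
        p["ch_g"],
        p["ch_E"],
        p["ch_kind"],
        p["ch_gstart"],
        p["ch_ng"],
        p["ch_kd"],
        p["ch_hill"],
        p["ch_feeds"],
        p["gp"],
        p["gate_comp"],
        v0,
        m0,
        state0,
        p["ca_par"],
        mode,
        np.ascontiguousarray(i_inj, dtype=float),
        np.ascontiguousarray(vcmd, dtype=float),
        syn_comp,
        g_ampa,
        g_nmda,
    )
    if status == _kernel.V_BLOWUP:
        raise IntegrationError(
            f"voltage blow-up (|V| > 200 mV) in compartment "
            f"{model.compartments[comp].label!r}; reduce dt or check conductances"
        )
    if status == _kernel.CA_NEGATIVE:
        raise IntegrationError("calcium shell driven negative; reduce dt")
    return v_out, aux


_BIAS_CACHE: dict = {}


def holding_bias(model: GrCModel, hold: float = -65.0, dt: float = DEFAULT_DT) -> float:
    """Constant somatic bias current (nA) holding the cell at ``hold`` mV.

    Mirrors the experimental practice of setting the membrane potential with
    a steady current.  Estimated from the steady-state ionic currents and
    refined with two short settling runs (secant step on the soma voltage).
    """
    key = (id(model.table), tuple(sorted(model.gmax_overrides.items())),
           model.trpm4_enabled, hold, dt, model.subtype_tag)
    if key in _BIAS_CACHE:
        return _BIAS_CACHE[key]
    p = model.packed()
    minf = _gate_steady_states(p, hold)
    ca_rest = p["ca_par"][2]
    i_tot = 0.0  # nA, outward positive
    for c in range(len(p["ch_comp"])):
        kind = p["ch_kind"][c]
        if kind == _kernel.KIND_HH:
            of = 1.0
            for k in range(p["ch_ng"][c]):
                j = p["ch_gstart"][c] + k
                of *= minf[j] ** p["gp"][j, _kernel.GP_EXP]
        elif kind == _kernel.KIND_CA_GATED:
            x = (ca_rest / p["ch_kd"][c]) ** p["ch_hill"][c]
            of = x / (1.0 + x)
        elif kind == _kernel.KIND_CAM_GATED:
            of = 0.0
        else:
            of = 1.0
        i_tot += p["ch_g"][c] * of * (hold - p["ch_E"][c])
    bias = i_tot

    def settle(b: float) -> float:
        n = int(round(400.0 / dt))
        v_out, _ = _run(model, 0, n, dt, i_inj=np.full(n, b), v_init=hold)
        return float(v_out[-1, 0])

    v1 = settle(bias)
    v2 = settle(bias + 0.005)
    slope = (v2 - v1) / 0.005  # mV per nA
    if abs(slope) > 1e-9:
        bias = bias + (hold - v1) / slope
    _BIAS_CACHE[key] = bias
    return bias


def simulate_current_clamp(
    model: GrCModel,
    i_inj: float,
    duration: float,
    hold: float = -65.0,
    dt: float = DEFAULT_DT,
    pre_ms: float = 200.0,
    post_ms: float = 0.0,
    record: Sequence[str] = ("soma",),
    syn: SynapticDrive | None = None,
    theta: float = 0.5,
) -> VoltageTrace:
    """2-s-style current-step simulation from a holding potential.

    ``i_inj`` in pA is applied for ``duration`` ms after ``pre_ms`` of
    settling at ``hold`` (maintained by an auto-computed bias current).
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    bias = holding_bias(model, hold, dt)
    n_pre = int(round(pre_ms / dt))
    n_stim = int(round(duration / dt))
    n_post = int(round(post_ms / dt))
    n = n_pre + n_stim + n_post
    i = np.full(n, bias)
    i[n_pre : n_pre + n_stim] += i_inj * 1e-3  # pA -> nA
    v_out, aux = _run(model, 0, n, dt, i_inj=i, v_init=hold, syn=syn, theta=theta)
    idx = model.comp_index
    data = {loc: v_out[:, idx[loc]].copy() for loc in record}
    return VoltageTrace(
        dt=dt,
        data=data,
        stim={
            "kind": "current_step",
            "amplitude_pA": i_inj,
            "onset_ms": pre_ms,
            "duration_ms": duration,
            "hold_mV": hold,
            "bias_nA": bias,
            "subtype": model.subtype_tag,
        },
        aux={
            "ca_nM": aux[:, _kernel.AUX_CA].copy(),
            "cam2c_nM": aux[:, _kernel.AUX_CAM2C].copy(),
            "trpm4_open": aux[:, _kernel.AUX_O].copy(),
            "i_trpm4_pA": aux[:, _kernel.AUX_ITRPM4].copy(),
        },
        unit="mV",
    )


def simulate_voltage_clamp(
    model: GrCModel,
    command: Sequence[tuple[float, float]] | np.ndarray,
    dt: float = DEFAULT_DT,
    record: Sequence[str] = ("soma",),
    syn: SynapticDrive | None = None,
) -> VoltageTrace:
    """Ideal somatic voltage clamp; returns the clamp current (pA).

    ``command`` is either a per-step voltage array or a piecewise-constant
    list of ``(duration_ms, level_mV)`` segments.
    """
    if isinstance(command, np.ndarray):
        vcmd = np.asarray(command, dtype=float)
    else:
        parts = [np.full(int(round(d / dt)), v) for d, v in command]
        if not parts:
            raise ValueError("command must cover a positive duration")
        vcmd = np.concatenate(parts)
    n = len(vcmd)
    v0 = float(vcmd[0])
    v_out, aux = _run(model, 1, n, dt, vcmd=vcmd, v_init=v0, syn=syn)
    i_clamp_pa = aux[:, _kernel.AUX_ICLAMP] * 1e3  # nA -> pA
    idx = model.comp_index
    data = {"clamp_current": i_clamp_pa.copy()}
    for loc in record:
        if loc != "soma":
            data[f"V_{loc}"] = v_out[:, idx[loc]].copy()
    return VoltageTrace(
        dt=dt,
        data=data,
        stim={"kind": "voltage_clamp", "command_mV": np.asarray(vcmd), "subtype": model.subtype_tag},
        aux={
            "ca_nM": aux[:, _kernel.AUX_CA].copy(),
            "cam2c_nM": aux[:, _kernel.AUX_CAM2C].copy(),
            "trpm4_open": aux[:, _kernel.AUX_O].copy(),
            "i_trpm4_pA": aux[:, _kernel.AUX_ITRPM4].copy(),
        },
        unit="pA",
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(
    model: GrCModel,
    i_inj: float = 10.0,
    duration: float = 2000.0,
    dt: float = DEFAULT_DT,
    probe_traces: VoltageTrace | None = None,
) -> tuple[bool, list[str]]:
    """Spike-generation/conduction screen applied to optimized models.

    Fails when (1) the AIS generates no spikes, (2) conduction along the
    ascending axon / parallel fiber is decremental (peak spike amplitude
    drops by more than 10 mV from AIS to axon ends), or (3) soma and axon
    firing rates differ by more than 1 spike/s.
    """
    from .features import detect_spikes

    required = ("soma", "AIS", "AA", "PF_right")
    if probe_traces is None:
        probe_traces = simulate_current_clamp(
            model, i_inj, duration, record=required, dt=dt
        )
    for loc in required:
        if loc not in probe_traces.data:
            raise ConfigurationError(f"validation requires a recording at {loc!r}")
    reasons = []
    spikes = {loc: detect_spikes(probe_traces, location=loc) for loc in required}
    if len(spikes["AIS"]) == 0:
        reasons.append("(1) spike generation in the AIS failed")
    else:
        peak_ais = float(np.max(probe_traces["AIS"]))
        for loc in ("AA", "PF_right"):
            if float(np.max(probe_traces[loc])) < peak_ais - 10.0:
                reasons.append(f"(2) decremental conduction into {loc}")
        window_s = duration / 1e3
        rate_soma = len(spikes["soma"]) / window_s
        rate_axon = len(spikes["PF_right"]) / window_s
        if abs(rate_soma - rate_axon) > 1.0:
            reasons.append(
                f"(3) soma rate {rate_soma:.1f} and axon rate {rate_axon:.1f} "
                "differ by more than 1 spike/s"
            )
    return (len(reasons) == 0, reasons)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _load_yaml(path: str | None, default_resource: str) -> dict:
    if path is None:
        text = resources.files("grcsim").joinpath(default_resource).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def load_model(subtype: str) -> GrCModel:
    """Load one of the calibrated reference subtype models."""
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}; expected one of {SUBTYPES}")
    return GrCModel.from_config(subtype=subtype)
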