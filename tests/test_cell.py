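"""Cell construction, passive correctness, simulation and validation."""

import numpy as np
import pytest

from grcsim.cell import (
    GrCModel,
    VoltageTrace,
    load_model,
    simulate_current_clamp,
    simulate_voltage_clamp,
    validate_model,
)
from grcsim.channels import ConfigurationError, load_channel_table
from grcsim.features import detect_spikes, spike_train_stats

PASSIVE_TABLE = """
channels:
  leak:
    reversal: -65.0
    kind: leak
    distribution:
      soma:       {gmax: 0.21}
      dendrite_1: {gmax: 0.21}
      dendrite_2: {gmax: 0.21}
      dendrite_3: {gmax: 0.21}
      dendrite_4: {gmax: 0.21}
      hillock:    {gmax: 0.21}
      AIS:        {gmax: 0.21}
      AA:         {gmax: 0.21}
      PF_left:    {gmax: 0.21}
      PF_right:   {gmax: 0.21}
"""


@pytest.fixture(scope="module")
def passive_model(tmp_path_factory):
    path = tmp_path_factory.mktemp("cfg") / "passive.yaml"
    path.write_text(PASSIVE_TABLE)
    return GrCModel.from_config(channel_table=load_channel_table(str(path)))


class TestConstruction:
    def test_whole_cell_capacitance_near_3_1_pF(self):
        model = GrCModel.from_config()
        assert model.total_capacitance_pf == pytest.approx(3.1, abs=0.15)

    def test_tree_rooted_at_soma_with_parents_first(self):
        model = GrCModel.from_config()
        idx = model.comp_index
        assert model.compartments[0].label == "soma"
        for c in model.compartments[1:]:
            assert idx[c.parent] < idx[c.label]

    def test_geometry_must_be_positive(self):
        from grcsim.cell import Compartment

        with pytest.raises(ConfigurationError):
            Compartment(label="soma", parent=None, length=-1.0, diameter=5.8)

    def test_gmax_vector_reflects_overrides(self):
        model = GrCModel.from_config().with_gmax({("Cav2.2", "soma"): 0.05})
        assert model.gmax_vector[("Cav2.2", "soma")] == pytest.approx(0.05)


class TestPassiveBehaviour:
    def test_steady_state_matches_analytic_cable_solution(self, passive_model):
        """With only leak conductances the model is linear; the somatic
        steady state under constant current must match the exact solution of
        the conductance matrix (independent dense solve)."""
        p = passive_model.packed()
        n = len(passive_model.compartments)
        G = np.zeros((n, n))
        for c in range(len(p["ch_comp"])):
            G[p["ch_comp"][c], p["ch_comp"][c]] += p["ch_g"][c]
        for i in range(1, n):
            j = p["parent"][i]
            G[i, i] += p["g_ax"][i]
            G[j, j] += p["g_ax"][i]
            G[i, j] -= p["g_ax"][i]
            G[j, i] -= p["g_ax"][i]
        i_inj = 0.005  # nA at the soma
        rhs = np.zeros(n)
        rhs[0] = i_inj
        dv = np.linalg.solve(G, rhs)  # deviation from -65 (leak reversal)
        trace = simulate_current_clamp(
            passive_model, i_inj * 1e3, 400.0, dt=0.025, pre_ms=50.0
        )
        v_end = trace["soma"][-1]
        assert v_end - (-65.0) == pytest.approx(dv[0], rel=1e-6)

    def test_subthreshold_charging_matches_rc_oracle(self, passive_model):
        """Compact passive cell: the somatic charging curve should follow a
        single-exponential RC within 5% of the steady-state deflection."""
        trace = simulate_current_clamp(
            passive_model, 5.0, 100.0, dt=0.01, pre_ms=50.0
        )
        t = trace.time - trace.onset
        sel = t >= 0
        v = trace["soma"][sel] - trace["soma"][int(trace.onset / trace.dt) - 1]
        t = t[sel]
        v_ss = v[-1]
        # effective tau from total capacitance and input resistance
        p = passive_model.packed()
        g_tot = sum(p["ch_g"])  # compact-limit conductance (uS)
        tau = sum(p["cap"]) / g_tot  # nF/uS = ms
        oracle = v_ss * (1.0 - np.exp(-t / tau))
        assert np.max(np.abs(v - oracle)) <= 0.05 * abs(v_ss)


class TestCurrentClamp:
    def test_silent_at_rest(self, models):
        for tag, m in models.items():
            tr = simulate_current_clamp(m, 0.0, 2000.0, dt=0.02)
            assert len(detect_spikes(tr)) == 0, tag
            assert tr["soma"][-1] == pytest.approx(-65.0, abs=1.0)

    def test_holding_potential_maintained_before_step(self, step_traces_10pa):
        for tag, tr in step_traces_10pa.items():
            pre = tr["soma"][: int(tr.onset / tr.dt)]
            assert np.max(np.abs(pre[-100:] - (-65.0))) < 1.0, tag

    def test_strong_adapting_slows_down(self, step_traces_10pa):
        st = spike_train_stats(step_traces_10pa["strong_adapting"])
        assert st.f_final < st.f_initial
        assert st.delta_f_0_2000 < -50.0

    def test_f_initial_monotone_in_current(self, models):
        """Early firing rate grows monotonically with injected current for
        every calibrated subtype (linear-ish f/I input-output)."""
        for tag, m in models.items():
            f = []
            for amp in (8.0, 12.0, 16.0, 20.0):
                tr = simulate_current_clamp(m, amp, 600.0, dt=0.02)
                st = detect_spikes(tr)
                f.append(np.sum((st >= 0) & (st < 500.0)) / 0.5)
            assert all(b >= a for a, b in zip(f, f[1:])), (tag, f)
            assert f[-1] > f[0], tag

    def test_negative_step_produces_no_spikes(self, models):
        for tag, m in models.items():
            tr = simulate_current_clamp(m, -8.0, 1000.0, dt=0.02)
            assert len(detect_spikes(tr)) == 0, tag

    def test_simulation_is_deterministic(self, models):
        m = models["non_adapting"]
        a = simulate_current_clamp(m, 10.0, 300.0, dt=0.02)
        b = simulate_current_clamp(m, 10.0, 300.0, dt=0.02)
        assert np.array_equal(a["soma"], b["soma"])

    def test_dt_halving_preserves_spike_count_and_early_times(self, models):
        """Step-size convergence at the default dt: halving dt changes the
        spike count by zero; early spike times agree within 0.1 ms.  (Late
        spike times in near-pause stretches of the adapting models are
        sensitive to the slow-variable phase and are checked on the stable
        regular-firing model.)"""
        for tag, m in models.items():
            a = detect_spikes(simulate_current_clamp(m, 10.0, 2000.0, dt=0.005))
            b = detect_spikes(simulate_current_clamp(m, 10.0, 2000.0, dt=0.0025))
            assert len(a) == len(b), tag
            k = int(np.sum(a < 500.0))  # stable early discharge
            assert np.max(np.abs(a[:k] - b[:k])) < 0.1, tag


class TestVoltageClamp:
    def test_clamp_at_rest_returns_holding_current_only(self, passive_model):
        trace = simulate_voltage_clamp(
            passive_model, [(200.0, -65.0)], dt=0.025
        )
        i = trace["clamp_current"]
        assert np.max(np.abs(i[10:])) < 0.5  # pA; rest = leak reversal

    def test_clamp_current_sign_on_depolarizing_step(self, passive_model):
        trace = simulate_voltage_clamp(
            passive_model, [(100.0, -65.0), (100.0, -55.0)], dt=0.025
        )
        i = trace["clamp_current"]
        # holding 10 mV above leak reversal requires steady outward current
        assert i[-1] > 0


class TestValidation:
    def test_calibrated_models_pass(self, models):
        for tag, m in models.items():
            ok, reasons = validate_model(m, dt=0.01)
            assert ok, (tag, reasons)

    def test_silencing_ais_sodium_fails_with_reason_1(self, models):
        broken = models["non_adapting"].with_gmax(
            {("Nav1.6", "AIS"): 0.0, ("Nav1.6+FHF", "AIS"): 0.0}
        )
        ok, reasons = validate_model(broken, dt=0.01)
        assert not ok
        assert any("(1)" in r for r in reasons)

    def test_missing_recording_location_is_configuration_error(self, models):
        tr = simulate_current_clamp(models["non_adapting"], 10.0, 300.0, dt=0.02)
        with pytest.raises(ConfigurationError):
            validate_model(models["non_adapting"], probe_traces=tr)


class TestTrace:
    def test_nonfinite_samples_rejected(self):
        with pytest.raises(ValueError):
            VoltageTrace(dt=0.1, data={"soma": np.array([0.0, np.nan])})

    def test_time_axis(self):
        tr = VoltageTrace(dt=0.5, data={"soma": np.zeros(5)})
        assert np.allclose(tr.time, [0.0, 0.5, 1.0, 1.5, 2.0])
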