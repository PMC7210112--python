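"""Spike detection and the firing statistics (IFC, SFC, S/N, eFeatures)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grcsim.cell import VoltageTrace
from grcsim.features import (
    acceleration_onset,
    delta_f,
    detect_spikes,
    extract_efeatures,
    intrinsic_frequency_change,
    signal_to_noise,
    spike_train_stats,
    synaptic_frequency_change,
    window_rate,
)


def make_spike_trace(spike_times_ms, dt=0.1, total_ms=2200.0, onset_ms=0.0):
    """Triangle spikes at prescribed times on a -65 mV baseline."""
    n = int(total_ms / dt)
    v = np.full(n, -65.0)
    for t in spike_times_ms:
        i = int((t + onset_ms) / dt)
        up = np.linspace(-65, 40, 10)
        down = np.linspace(40, -70, 15)
        v[i - 10 : i] = up
        v[i : i + 15] = down
    return VoltageTrace(
        dt=dt,
        data={"soma": v},
        stim={"onset_ms": onset_ms, "duration_ms": total_ms - onset_ms},
    )


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        tr = VoltageTrace(dt=0.1, data={"soma": np.full(1000, -65.0)})
        assert len(detect_spikes(tr)) == 0

    def test_three_sawtooth_spikes_detected(self, synthetic_spike_trace):
        tr, peaks = synthetic_spike_trace
        st_ = detect_spikes(tr)
        assert len(st_) == 3
        assert np.max(np.abs(st_ - peaks)) < 2.5  # threshold crossing leads peak

    def test_agreement_with_peak_finding_oracle(self, step_traces_10pa):
        """Counts must agree with an independent scipy peak finder on real
        simulated traces from all four subtypes."""
        from scipy.signal import find_peaks

        for tag, tr in step_traces_10pa.items():
            ours = detect_spikes(tr)
            peaks, _ = find_peaks(tr["soma"], height=-20.0, distance=int(1.0 / tr.dt))
            assert len(ours) == len(peaks), tag

    def test_nan_rejected(self):
        v = np.full(100, -65.0)
        v[3] = np.nan
        tr = VoltageTrace.__new__(VoltageTrace)  # bypass finite check
        object.__setattr__(tr, "dt", 0.1)
        object.__setattr__(tr, "data", {"soma": v})
        object.__setattr__(tr, "stim", {})
        with pytest.raises(ValueError):
            detect_spikes(tr)


class TestFrequencyChanges:
    @pytest.mark.parametrize(
        "f_init,f_fin,expected",
        [(50.0, 50.0, 0.0), (50.0, 25.0, -50.0), (26.0, 51.0, 96.15384615)],
    )
    def test_ifc_formula(self, f_init, f_fin, expected):
        assert intrinsic_frequency_change(f_init, f_fin) == pytest.approx(expected)

    def test_ifc_undefined_for_silent_initial_window(self):
        assert intrinsic_frequency_change(0.0, 10.0) is None

    @pytest.mark.parametrize(
        "f_resp,f_stim,expected", [(20.0, 20.0, 0.0), (10.0, 20.0, -50.0), (24.0, 20.0, 20.0)]
    )
    def test_sfc_formula(self, f_resp, f_stim, expected):
        assert synaptic_frequency_change(f_resp, f_stim) == pytest.approx(expected)

    def test_sfc_requires_positive_stimulus_rate(self):
        with pytest.raises(ValueError):
            synaptic_frequency_change(10.0, 0.0)

    @given(
        f=st.floats(1.0, 200.0), g=st.floats(0.0, 200.0), c=st.floats(0.1, 10.0)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance(self, f, g, c):
        a = intrinsic_frequency_change(f, g)
        b = intrinsic_frequency_change(c * f, c * g)
        assert a == pytest.approx(b, rel=1e-9)
        assert synaptic_frequency_change(g, f) == pytest.approx(
            synaptic_frequency_change(c * g, c * f), rel=1e-9
        )

    def test_identity_gives_exact_zero(self):
        assert intrinsic_frequency_change(37.0, 37.0) == 0.0
        assert synaptic_frequency_change(37.0, 37.0) == 0.0


class TestSignalToNoise:
    def test_plain_ratio(self):
        assert signal_to_noise(30.0, 3.0) == pytest.approx(10.0)

    def test_identity_is_one(self):
        assert signal_to_noise(12.0, 12.0) == 1.0

    def test_silent_background_is_infinite(self):
        assert math.isinf(signal_to_noise(10.0, 0.0))

    def test_both_silent_is_undefined(self):
        assert math.isnan(signal_to_noise(0.0, 0.0))


class TestSpikeTrainStats:
    def test_window_statistics_on_constructed_train(self):
        # 40 Hz in 0-500 ms, 20 Hz in 1500-2000 ms
        times = np.concatenate(
            [np.arange(10.0, 500.0, 25.0), np.arange(1510.0, 2000.0, 50.0)]
        )
        tr = make_spike_trace(times)
        s = spike_train_stats(tr)
        assert s.f_initial == pytest.approx(40.0)
        assert s.f_final == pytest.approx(20.0)
        assert s.delta_f_0_2000 == pytest.approx(-50.0)

    def test_padding_insensitivity(self):
        """Statistics are computed relative to stimulus onset, so adding
        pre-stimulus padding must not change them."""
        times = np.arange(10.0, 2000.0, 25.0)
        a = spike_train_stats(make_spike_trace(times, onset_ms=0.0))
        b = spike_train_stats(make_spike_trace(times, onset_ms=150.0))
        assert a.f_initial == b.f_initial
        assert a.f_final == b.f_final
        assert a.delta_f_0_2000 == pytest.approx(b.delta_f_0_2000)

    def test_window_rate_rejects_empty_window(self):
        with pytest.raises(ValueError):
            window_rate(np.array([1.0]), 100.0, 100.0)


class TestAccelerationOnset:
    def test_regular_train_never_flags_onset(self):
        tr = make_spike_trace(np.arange(10.0, 2000.0, 25.0))
        assert acceleration_onset(tr) is None

    def test_onset_found_where_rate_doubles(self):
        times = np.concatenate(
            [np.arange(10.0, 1500.0, 40.0), np.arange(1510.0, 2000.0, 15.0)]
        )
        tr = make_spike_trace(times)
        onset = acceleration_onset(tr)
        assert onset is not None
        assert 1500.0 <= onset <= 1650.0


class TestEFeatures:
    def test_identical_spikes_have_zero_cv_and_adaptation(self):
        tr = make_spike_trace(np.arange(50.0, 2000.0, 50.0))
        f = extract_efeatures(tr)
        assert f.isi_cv == pytest.approx(0.0, abs=1e-12)
        assert f.adaptation_index == pytest.approx(0.0, abs=1e-12)
        assert f.time_to_first_spike == pytest.approx(50.0, abs=2.0)

    def test_lengthening_isis_give_positive_adaptation_index(self):
        isis = np.array([20.0, 25.0, 31.25, 39.0, 48.8])
        times = 50.0 + np.concatenate([[0.0], np.cumsum(isis)])
        tr = make_spike_trace(times)
        f = extract_efeatures(tr)
        expected = np.mean((isis[1:] - isis[:-1]) / (isis[1:] + isis[:-1]))
        assert f.adaptation_index == pytest.approx(expected, rel=1e-6)

    def test_resting_potential_of_held_model(self, step_traces_10pa):
        for tag, tr in step_traces_10pa.items():
            f = extract_efeatures(tr)
            assert f.resting_potential == pytest.approx(-65.0, abs=1.0), tag

    def test_no_spikes_marks_shape_features_undefined(self):
        tr = VoltageTrace(
            dt=0.1,
            data={"soma": np.full(1000, -65.0)},
            stim={"onset_ms": 0.0, "duration_ms": 100.0},
        )
        f = extract_efeatures(tr)
        assert f.spike_width is None and f.spike_height is None
        assert f.mean_frequency == 0.0

    def test_spike_shape_features_positive_on_simulated_trace(self, step_traces_10pa):
        f = extract_efeatures(step_traces_10pa["non_adapting"])
        assert f.spike_width > 0 and f.spike_height > 0
        assert f.fast_ahp_depth is not None
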