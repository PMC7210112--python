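"""Spike detection and the firing statistics used throughout the pipeline.

Definitions
-----------
* f_initial, f_final: spike counts in the 0-500 ms and 1500-2000 ms windows
  of a 2-s current step, divided by 0.5 s (window counts, not inverse ISI).
* IFC (intrinsic frequency change) = (f_final - f_initial)/f_initial * 100;
  negative = adaptation, positive = acceleration.
* SFC (synaptic frequency change) = (f_resp - f_stim)/f_stim * 100.
* S/N = response rate during a 100 Hz burst / response rate during the
  20 Hz background.
* Delta-f windows: percent change between consecutive sub-windows of the
  early response (stability check).

Features that are undefined (no spikes, zero denominators) propagate as
``None`` / NaN markers, never as silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cell import VoltageTrace

__all__ = [
    "SpikeTrainStats",
    "CellFeatures",
    "EFeatureVector",
    "detect_spikes",
    "window_rate",
    "spike_train_stats",
    "intrinsic_frequency_change",
    "delta_f",
    "synaptic_frequency_change",
    "signal_to_noise",
    "extract_efeatures",
    "acceleration_onset",
]

SPIKE_THRESHOLD = -20.0  # mV, upward crossing
REFRACTORY_MS = 1.0

#: the two 500-ms windows of the 2-s step protocol (ms from stimulus onset)
WINDOW_INITIAL = (0.0, 500.0)
WINDOW_FINAL = (1500.0, 2000.0)


@dataclass(frozen=True)
class SpikeTrainStats:
    spike_times: np.ndarray      # ms from stimulus onset
    f_initial: float             # Hz over 0-500 ms
    f_final: float               # Hz over 1500-2000 ms
    delta_f_0_500: float | None  # % change across the two halves of 0-500 ms
    delta_f_0_2000: float | None  # % change 0-500 vs 1500-2000 (== IFC)
    isi_cv: float | None


@dataclass(frozen=True)
class CellFeatures:
    """Per-cell feature bundle feeding clustering and population plots."""

    ifc_at_10pa: float | None
    f_initial_at_10pa: float | None
    sfc_per_rate: dict | None = None
    s_n: float | None = None
    ppr: float | None = None
    label: str | None = None


@dataclass(frozen=True)
class EFeatureVector:
    resting_potential: float          # mV
    spike_width: float | None         # ms at half height
    spike_height: float | None        # mV, peak minus threshold
    fast_ahp_depth: float | None      # mV below threshold
    slow_ahp_depth: float | None      # mV below threshold
    mean_frequency: float             # Hz over the stimulus window
    time_to_first_spike: float | None  # ms from onset
    adaptation_index: float | None
    isi_cv: float | None

    def as_array(self) -> np.ndarray:
        vals = [
            self.resting_potential,
            self.spike_width,
            self.spike_height,
            self.fast_ahp_depth,
            self.slow_ahp_depth,
            self.mean_frequency,
            self.time_to_first_spike,
            self.adaptation_index,
            self.isi_cv,
        ]
        return np.array([np.nan if v is None else v for v in vals], dtype=float)

    @staticmethod
    def names() -> tuple[str, ...]:
        return (
            "resting_potential",
            "spike_width",
            "spike_height",
            "fast_ahp_depth",
            "slow_ahp_depth",
            "mean_frequency",
            "time_to_first_spike",
            "adaptation_index",
            "isi_cv",
        )


def detect_spikes(
    trace: VoltageTrace,
    threshold: float = SPIKE_THRESHOLD,
    location: str = "soma",
    refractory: float = REFRACTORY_MS,
) -> np.ndarray:
    """Spike times (ms from *stimulus onset*) as upward threshold crossings
    with a refractory guard."""
    v = np.asarray(trace[location], dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("NaN in voltage trace")
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(crossings) == 0:
        return np.zeros(0)
    keep = [crossings[0]]
    min_gap = refractory / trace.dt
    for c in crossings[1:]:
        if c - keep[-1] >= min_gap:
            keep.append(c)
    return np.array(keep) * trace.dt - trace.onset


def window_rate(spike_times: np.ndarray, t0: float, t1: float) -> float:
    """Firing rate (Hz) as spike count in [t0, t1) ms divided by the window."""
    if t1 <= t0:
        raise ValueError("empty window")
    n = int(np.sum((spike_times >= t0) & (spike_times < t1)))
    return n / ((t1 - t0) / 1e3)


def intrinsic_frequency_change(f_initial: float, f_final: float) -> float | None:
    """IFC = (f_final - f_initial)/f_initial in %; None when undefined."""
    if f_initial <= 0:
        return None
    return (f_final - f_initial) / f_initial * 100.0


def delta_f(f_a: float, f_b: float) -> float | None:
    """Percent change from f_a to f_b; None when f_a == 0."""
    if f_a <= 0:
        return None
    return (f_b - f_a) / f_a * 100.0


def synaptic_frequency_change(f_resp: float, f_stim: float) -> float:
    """SFC = (f_resp - f_stim)/f_stim in %."""
    if f_stim <= 0:
        raise ValueError("f_stim must be > 0")
    return (f_resp - f_stim) / f_stim * 100.0


def signal_to_noise(f_resp_burst: float, f_resp_bkg: float) -> float:
    """S/N = burst-response rate / background-response rate.

    Returns ``inf`` when the background rate is zero but the burst responds,
    ``nan`` when both are zero (undefined).
    """
    if f_resp_bkg <= 0:
        return math.nan if f_resp_burst <= 0 else math.inf
    return f_resp_burst / f_resp_bkg


def _isi_cv(isis: np.ndarray) -> float | None:
    if len(isis) < 2:
        return None
    mu = float(np.mean(isis))
    return float(np.std(isis) / mu) if mu > 0 else None


def spike_train_stats(trace: VoltageTrace, location: str = "soma") -> SpikeTrainStats:
    """All window statistics of a 2-s current-step response."""
    st = detect_spikes(trace, location=location)
    st = st[st >= 0]
    f_init = window_rate(st, *WINDOW_INITIAL)
    f_fin = window_rate(st, *WINDOW_FINAL)
    f_q1 = window_rate(st, 0.0, 250.0)
    f_q2 = window_rate(st, 250.0, 500.0)
    isis = np.diff(st)
    return SpikeTrainStats(
        spike_times=st,
        f_initial=f_init,
        f_final=f_fin,
        delta_f_0_500=delta_f(f_q1, f_q2),
        delta_f_0_2000=intrinsic_frequency_change(f_init, f_fin),
        isi_cv=_isi_cv(isis),
    )


def acceleration_onset(
    trace: VoltageTrace, location: str = "soma", rel_increase: float = 0.2
) -> float | None:
    """Latency (ms from onset) at which the instantaneous rate first exceeds
    the 0-500 ms mean rate by ``rel_increase`` (smoothed over 3 ISIs).

    Returns None when the discharge never accelerates.
    """
    st = detect_spikes(trace, location=location)
    st = st[st >= 0]
    if len(st) < 5:
        return None
    f_init = window_rate(st, *WINDOW_INITIAL)
    if f_init <= 0:
        return None
    isis = np.diff(st)
    inst = 1e3 / isis  # Hz
    smooth = np.convolve(inst, np.ones(3) / 3.0, mode="valid")
    t_smooth = st[3:]  # time of the last spike entering each smoothed value
    above = smooth > f_init * (1.0 + rel_increase)
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return None
    return float(t_smooth[idx[0]])


def extract_efeatures(
    trace: VoltageTrace,
    location: str = "soma",
    threshold: float = SPIKE_THRESHOLD,
) -> EFeatureVector:
    """eFEL-style scalar features of a current-step response.

    Spike height/width are measured on the somatic waveform; the fast AHP is
    the minimum within 5 ms of a spike peak, the slow AHP the minimum over
    the remaining ISI.  The adaptation index is the mean of
    (ISI[i+1]-ISI[i])/(ISI[i+1]+ISI[i]) (eFEL convention).
    """
    v = np.asarray(trace[location], dtype=float)
    dt = trace.dt
    onset_idx = int(round(trace.onset / dt))
    rest = float(np.mean(v[max(0, onset_idx - int(50 / dt)) : max(1, onset_idx)]))
    st = detect_spikes(trace, threshold=threshold, location=location)
    st = st[st >= 0]
    stim_dur = float(trace.stim.get("duration_ms", trace.time[-1] - trace.onset))
    mean_freq = len(st) / (stim_dur / 1e3) if stim_dur > 0 else 0.0
    if len(st) == 0:
        return EFeatureVector(rest, None, None, None, None, mean_freq, None, None, None)

    idxs = ((st + trace.onset) / dt).astype(int)
    widths, heights, fast_ahps, slow_ahps = [], [], [], []
    for k, i0 in enumerate(idxs):
        i1 = idxs[k + 1] if k + 1 < len(idxs) else min(len(v), i0 + int(20 / dt))
        seg = v[i0:i1]
        if len(seg) < 3:
            continue
        pk = int(np.argmax(seg))
        peak = float(seg[pk])
        heights.append(peak - threshold)
        half = (peak + threshold) / 2.0
        above = seg >= half
        widths.append(float(np.sum(above)) * dt)
        i_fast_end = min(len(seg), pk + int(5.0 / dt))
        if i_fast_end > pk + 1:
            fast_ahps.append(threshold - float(np.min(seg[pk:i_fast_end])))
        if k + 1 < len(idxs) and len(seg) > i_fast_end:
            slow_ahps.append(threshold - float(np.min(seg[i_fast_end:])))
    isis = np.diff(st)
    if len(isis) >= 2:
        adap = float(np.mean((isis[1:] - isis[:-1]) / (isis[1:] + isis[:-1])))
    else:
        adap = None
    return EFeatureVector(
        resting_potential=rest,
        spike_width=float(np.mean(widths)) if widths else None,
        spike_height=float(np.mean(heights)) if heights else None,
        fast_ahp_depth=float(np.mean(fast_ahps)) if fast_ahps else None,
        slow_ahp_depth=float(np.mean(slow_ahps)) if slow_ahps else None,
        mean_frequency=mean_freq,
        time_to_first_spike=float(st[0]),
        adaptation_index=adap,
        isi_cv=_isi_cv(isis),
    )
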