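"""Simulate the four calibrated granule-cell subtype models at 10 pA and
print their firing statistics.

IFC = (f_final - f_initial)/f_initial in %, from the 0-500 ms and
1500-2000 ms windows of a 2 s step: negative values mean the cell adapts
(slows down), positive values that it accelerates.  Delta-f(0-500) is the
rate change across the two halves of the first 500 ms — small for every
subtype, which is why short protocols made granule cells look uniform.
"""

from grcsim import SUBTYPES, load_model, simulate_current_clamp, spike_train_stats

print(f"{'subtype':18s} {'f_initial':>9s} {'f_final':>8s} {'IFC %':>8s} {'df0-500 %':>10s}")
for tag in SUBTYPES:
    model = load_model(tag)
    trace = simulate_current_clamp(model, 10.0, 2000.0)
    s = spike_train_stats(trace)
    print(
        f"{tag:18s} {s.f_initial:9.1f} {s.f_final:8.1f} "
        f"{s.delta_f_0_2000:8.1f} {s.delta_f_0_500:10.1f}"
    )
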