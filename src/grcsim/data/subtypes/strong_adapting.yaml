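# Strong-adapting reference model: large Cav2.2 density drives Ca accumulation
# and the slow Ca-gated K current, deeply suppressing (even stopping) late
# firing (IFC ~ -70 to -90%).
tag: strong_adapting
trpm4_enabled: false
gmax:
  Cav2.2: {soma: 0.026}
  KCa1.1: {soma: 1.0}
  Kv1.1:  {soma: 1.2}
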