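# Non-adapting reference model: small Cav2.2 density, late firing nearly
# equals early firing (IFC ~ -10%).
tag: non_adapting
trpm4_enabled: false
gmax:
  Cav2.2: {soma: 0.008}
  KCa1.1: {soma: 0.60}
  Kv1.1:  {soma: 1.2}
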