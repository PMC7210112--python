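# Mild-adapting reference model: intermediate Cav2.2 density (IFC ~ -40%).
tag: mild_adapting
trpm4_enabled: false
gmax:
  Cav2.2: {soma: 0.017}
  KCa1.1: {soma: 0.60}
  Kv1.1:  {soma: 1.2}
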