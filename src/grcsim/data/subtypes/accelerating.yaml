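# Accelerating reference model: TRPM4 coupled to Ca/Calmodulin; no slow
# Ca-gated K current.  CaM2C crosses threshold ~1.5 s into a 10 pA discharge
# and the TRPM4 inward current roughly doubles the firing rate (IFC ~ +96%).
tag: accelerating
trpm4_enabled: true
gmax:
  Cav2.2: {soma: 0.029}
  KCa1.1: {soma: 0.0}
  TRPM4:  {soma: 0.80}
  Kv1.1:  {soma: 1.2}
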