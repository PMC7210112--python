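# Default granule-cell model: morphology, passive properties and the
# Ca2+/Calmodulin/TRPM4 coupling parameters.  Geometry is a canonical
# granule-cell surrogate (small soma, four short dendrites, thin axon with
# hillock, initial segment, ascending axon and two parallel-fiber branches)
# sized so the whole-cell capacitance lands near the experimental 3.1 pF.
# Lengths/diameters in um, resistivity in Ohm*cm, cm in uF/cm^2.

morphology:
  soma:       {parent: null,  length: 5.8,  diameter: 5.8}
  dendrite_1: {parent: soma,  length: 15.0, diameter: 0.55}
  dendrite_2: {parent: soma,  length: 15.0, diameter: 0.55}
  dendrite_3: {parent: soma,  length: 15.0, diameter: 0.55}
  dendrite_4: {parent: soma,  length: 15.0, diameter: 0.55}
  hillock:    {parent: soma,  length: 2.3,  diameter: 1.5}
  AIS:        {parent: hillock, length: 10.0, diameter: 0.7}
  AA:         {parent: AIS,   length: 60.0, diameter: 0.2}
  PF_left:    {parent: AA,    length: 30.0, diameter: 0.15}
  PF_right:   {parent: AA,    length: 30.0, diameter: 0.15}

passive:
  axial_resistivity: 100.0
  cm: 1.0
  cm_target_pf: 3.1      # whole-cell capacitance target (band +-0.15 pF)
  rm_target_gohm: 1.1

calcium:
  shell_depth: 0.3       # um
  ca_rest: 100.0         # nM
  extrusion_rate: 0.05   # 1/ms (shell Ca integrates over a few ISIs)
  buffer_total: 10000.0  # nM, Calretinin-like single-site buffer
  buffer_kon: 1.0e-5     # 1/(nM*ms)
  buffer_koff: 0.005      # 1/ms

calmodulin:
  cam_total: 10000.0     # nM
  kon2: 2.0e-11          # 1/(nM^2*ms), cooperative forward rate
  koff2: 1.0e-4          # 1/ms

trpm4:
  cam2c_threshold: 40.0  # nM
  hill_n: 10.0
  act_tau: 300.0         # ms
  deact_tau: 1000.0      # ms
  kca_tau: 1400.0        # ms, total two-stage activation lag of the Ca-gated K channel
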