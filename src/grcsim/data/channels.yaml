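# Channel table for the granule-cell model: gating kinetics, reversal
# potentials, compartment distribution and conductance-density bounds.
# This file is the single source of truth for the optimizer's search space.
#
# Gates: x_inf(V) = floor + (1-floor)/(1+exp(-(V-vhalf)/slope))
#        tau(V)   = tau_min + tau_amp/(exp((V-tau_vhalf)/tau_s1)
#                                      + exp(-(V-tau_vhalf)/tau_s2))  [ms]
# slope < 0 marks inactivation gates.  Time constants are given at 32 C
# (t_ref: 32), the temperature of the recordings and simulations, so the
# Q10 correction is the identity at the default simulation temperature.
# Units: mV, ms, mS/cm^2.  Densities are Hodgkin-Huxley-style fits chosen
# for the granule-cell channel families; they are editable data.

channels:
  Nav1.6:
    reversal: 60.0
    gates:
      - {name: m, exponent: 3, vhalf: -42.0, slope: 5.5,
         tau_min: 0.05, tau_amp: 0.4, tau_vhalf: -38.0, tau_s1: 12.0, tau_s2: 12.0,
         q10: 3.0, t_ref: 32.0}
      - {name: h, exponent: 1, vhalf: -52.0, slope: -5.5,
         tau_min: 0.25, tau_amp: 25.0, tau_vhalf: -55.0, tau_s1: 12.0, tau_s2: 12.0,
         q10: 3.0, t_ref: 32.0}
    distribution:
      soma:    {gmax: 8.0,   bounds: [1.0, 30.0]}
      hillock: {gmax: 60.0,  bounds: [0.0, 200.0]}
      AIS:     {gmax: 400.0, bounds: [0.0, 800.0]}
      AA:      {gmax: 40.0,  bounds: [0.0, 120.0]}
      PF_left: {gmax: 40.0,  bounds: [0.0, 120.0]}
      PF_right: {gmax: 40.0, bounds: [0.0, 120.0]}

  # FHF-modulated Nav1.6: right-shifted, incomplete inactivation yielding a
  # small persistent component that sustains repetitive firing.
  Nav1.6+FHF:
    reversal: 60.0
    gates:
      - {name: m, exponent: 3, vhalf: -42.0, slope: 5.5,
         tau_min: 0.05, tau_amp: 0.4, tau_vhalf: -38.0, tau_s1: 12.0, tau_s2: 12.0,
         q10: 3.0, t_ref: 32.0}
      - {name: h, exponent: 1, vhalf: -47.0, slope: -6.0, floor: 0.04,
         tau_min: 0.25, tau_amp: 25.0, tau_vhalf: -50.0, tau_s1: 12.0, tau_s2: 12.0,
         q10: 3.0, t_ref: 32.0}
    distribution:
      soma: {gmax: 1.0, bounds: [0.0, 6.0]}
      AIS:  {gmax: 15.0, bounds: [0.0, 60.0]}

  Kv1.1:
    reversal: -85.0
    gates:
      - {name: n, exponent: 1, vhalf: -40.0, slope: 8.0,
         tau_min: 1.0, tau_amp: 15.0, tau_vhalf: -40.0, tau_s1: 20.0, tau_s2: 20.0,
         q10: 3.0, t_ref: 32.0}
    distribution:
      soma:    {gmax: 0.3, bounds: [0.0, 2.0]}
      hillock: {gmax: 1.0, bounds: [0.0, 6.0]}
      AIS:     {gmax: 2.0, bounds: [0.0, 12.0]}

  Kv1.5:
    reversal: -85.0
    gates:
      - {name: n, exponent: 1, vhalf: -30.0, slope: 8.0,
         tau_min: 2.0, tau_amp: 20.0, tau_vhalf: -30.0, tau_s1: 20.0, tau_s2: 20.0,
         q10: 3.0, t_ref: 32.0}
    distribution:
      soma: {gmax: 0.3, bounds: [0.0, 2.0]}

  Kv2:
    reversal: -85.0
    gates:
      - {name: n, exponent: 2, vhalf: -30.0, slope: 9.0,
         tau_min: 1.0, tau_amp: 30.0, tau_vhalf: -30.0, tau_s1: 18.0, tau_s2: 18.0,
         q10: 3.0, t_ref: 32.0}
    distribution:
      soma: {gmax: 2.0, bounds: [0.0, 10.0]}

  # A-type: fast activation, hyperpolarization-primed inactivation gate.
  Kv4.3:
    reversal: -85.0
    gates:
      - {name: a, exponent: 3, vhalf: -46.0, slope: 14.0,
         tau_min: 0.4, tau_amp: 2.0, tau_vhalf: -45.0, tau_s1: 20.0, tau_s2: 20.0,
         q10: 3.0, t_ref: 32.0}
      - {name: b, exponent: 1, vhalf: -69.0, slope: -7.0,
         tau_min: 8.0, tau_amp: 40.0, tau_vhalf: -65.0, tau_s1: 20.0, tau_s2: 20.0,
         q10: 3.0, t_ref: 32.0}
    distribution:
      soma:       {gmax: 1.0, bounds: [0.0, 12.0]}
      dendrite_1: {gmax: 1.0, bounds: [0.0, 12.0]}
      dendrite_2: {gmax: 1.0, bounds: [0.0, 12.0]}
      dendrite_3: {gmax: 1.0, bounds: [0.0, 12.0]}
      dendrite_4: {gmax: 1.0, bounds: [0.0, 12.0]}

  # fast high-threshold repolarizer
  Kv3.4:
    reversal: -85.0
    gates:
      - {name: n, exponent: 2, vhalf: -25.0, slope: 9.0,
         tau_min: 0.3, tau_amp: 8.0, tau_vhalf: -30.0, tau_s1: 15.0, tau_s2: 15.0,
         q10: 3.0, t_ref: 32.0}
    distribution:
      soma:    {gmax: 6.0,  bounds: [1.0, 30.0]}
      hillock: {gmax: 10.0, bounds: [1.0, 40.0]}
      AIS:     {gmax: 60.0, bounds: [10.0, 200.0]}
      AA:      {gmax: 12.0, bounds: [2.0, 40.0]}
      PF_left: {gmax: 12.0, bounds: [2.0, 40.0]}
      PF_right: {gmax: 12.0, bounds: [2.0, 40.0]}

  # M-type: slow, non-inactivating, sub-threshold
  Kv7:
    reversal: -85.0
    gates:
      - {name: n, exponent: 1, vhalf: -38.0, slope: 7.0,
         tau_min: 20.0, tau_amp: 300.0, tau_vhalf: -40.0, tau_s1: 20.0, tau_s2: 20.0,
         q10: 3.0, t_ref: 32.0}
    distribution:
      soma: {gmax: 0.25, bounds: [0.0, 1.5]}
      AIS:  {gmax: 0.5,  bounds: [0.0, 3.0]}

  # N-type high-voltage-activated Ca channel; its current is routed into the
  # submembrane Ca shell (it never contributes Ca to the voltage equation only).
  Cav2.2:
    reversal: 60.0
    feeds_ca_shell: true
    gates:
      - {name: m, exponent: 2, vhalf: -22.0, slope: 6.0,
         tau_min: 0.2, tau_amp: 1.5, tau_vhalf: -25.0, tau_s1: 15.0, tau_s2: 15.0,
         q10: 3.0, t_ref: 32.0}
    distribution:
      soma: {gmax: 0.02, bounds: [0.002, 0.12]}

  # Ca-activated K channel (Hill function of shell Ca), the main coupling
  # from Cav2.2 influx to spike-frequency adaptation.
  KCa1.1:
    reversal: -85.0
    kind: ca_gated
    ligand_kd: 400.0      # nM
    ligand_hill: 4.0
    distribution:
      soma: {gmax: 0.4, bounds: [0.0, 8.0]}

  # CaM2C-gated, Ca-impermeable nonselective cation channel (E_rev ~ 0 mV).
  # Open fraction dynamics live in the calcium/CaM module; density here.
  TRPM4:
    reversal: 0.0
    kind: cam_gated
    distribution:
      soma: {gmax: 0.0, bounds: [0.0, 1.0]}

  leak:
    reversal: -65.0
    kind: leak
    distribution:
      soma:       {gmax: 0.21, bounds: [0.05, 1.0]}
      dendrite_1: {gmax: 0.21, bounds: [0.05, 1.0]}
      dendrite_2: {gmax: 0.21, bounds: [0.05, 1.0]}
      dendrite_3: {gmax: 0.21, bounds: [0.05, 1.0]}
      dendrite_4: {gmax: 0.21, bounds: [0.05, 1.0]}
      hillock:    {gmax: 0.21, bounds: [0.05, 1.0]}
      AIS:        {gmax: 0.21, bounds: [0.05, 1.0]}
      AA:         {gmax: 0.21, bounds: [0.05, 1.0]}
      PF_left:    {gmax: 0.21, bounds: [0.05, 1.0]}
      PF_right:   {gmax: 0.21, bounds: [0.05, 1.0]}
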