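# Cerebellar granule cell, multi-compartment conductance-based model.
#
# Kinetic equations of the granule-cell model family (transient + persistent
# Na, delayed-rectifier and A-type K, inward rectifier, high-threshold Ca,
# Ca-activated K, ohmic + GABA-A leak) encoded as Boltzmann steady-state /
# time-constant or bounded-rate forms and calibrated so that, at the 30 °C
# simulation temperature, the control model rests at -70 mV and fires with the
# documented -47 mV threshold under step-current injection.
#
# Units: lengths um, densities S/cm2, voltages mV, times ms, capacitance
# uF/cm2, axial resistivity ohm*cm.
schema_version: 1
cell: grc
resting_potential_mV: -70.0
capacitance_uF_per_cm2: 1.0
axial_resistivity_ohm_cm: 100.0

# Intracellular Ca diffusion Q10 ambiguity in the source material: recorded
# both readings; the granule cell uses 1.3.
q10_ca_diffusion: {grc: 1.3, goc: 1.7}

compartments:
  - {name: soma,    role: soma,     parent: null,    length_um: 5.8,  diameter_um: 5.8}
  - {name: dend1,   role: dendrite, parent: soma,    length_um: 15.0, diameter_um: 0.6}
  - {name: dend2,   role: dendrite, parent: soma,    length_um: 15.0, diameter_um: 0.6}
  - {name: dend3,   role: dendrite, parent: soma,    length_um: 15.0, diameter_um: 0.6}
  - {name: dend4,   role: dendrite, parent: soma,    length_um: 15.0, diameter_um: 0.6}
  - {name: hillock, role: hillock,  parent: soma,    length_um: 2.0,  diameter_um: 1.5}
  # tapered ascending axon, four segments: the spike initiates in the thin
  # distal segments and invades the soma through the thicker proximal ones,
  # as in the detailed granule-cell models this encoding follows
  - {name: axon1,   role: axon,     parent: hillock, length_um: 50.0, diameter_um: 0.4}
  - {name: axon2,   role: axon,     parent: axon1,   length_um: 50.0, diameter_um: 0.3}
  - {name: axon3,   role: axon,     parent: axon2,   length_um: 50.0, diameter_um: 0.2}
  - {name: axon4,   role: axon,     parent: axon3,   length_um: 50.0, diameter_um: 0.2}

channels:
  na_t:                       # transient Na (spike generator)
    erev_mV: 87.4
    t_orig_C: 37.0
    density_S_per_cm2: {hillock: 0.03, axon1: 0.02, axon2: 0.02, axon3: 0.02, axon4: 0.02}
    gates:
      - {name: m, form: inf_tau, exponent: 3,
         params: {vhalf: -36.0, k: 5.5, tau_min: 0.03, tau_amp: 0.20, vtau: -40.0, sigma: 18.0}}
      - {name: h, form: inf_tau, exponent: 1,
         params: {vhalf: -52.0, k: -4.0, tau_min: 0.25, tau_amp: 7.0, vtau: -55.0, sigma: 12.0}}
  na_p:                       # persistent Na (threshold setter), distal axon
    erev_mV: 87.4
    t_orig_C: 37.0
    density_S_per_cm2: {axon3: 0.002, axon4: 0.002}
    kinetics: {a_on: 0.75, a_off: 0.005}      # on/off kinetic time scales, ms
    gate_shape: {v0: -36.2, ka: 10.0, kb: 10.0, a_mag: 1.2, b_mag: 0.00536}
    gates:                    # slow inactivation bounding the window current
      - {name: s, form: inf_tau, exponent: 1,
         params: {vhalf: -63.0, k: -2.5, tau_min: 60.0, tau_amp: 0.0, vtau: -60.0, sigma: 20.0}}
  kv:                         # delayed rectifier K
    erev_mV: -84.7
    t_orig_C: 37.0
    density_S_per_cm2: {hillock: 0.003, axon1: 0.003, axon2: 0.003, axon3: 0.003, axon4: 0.003}
    gates:
      - {name: n, form: inf_tau, exponent: 4,
         params: {vhalf: -38.0, k: 8.0, tau_min: 0.25, tau_amp: 2.0, vtau: -50.0, sigma: 20.0}}
  k_slow:                     # slow M-type K (hillock/axon); bounds sustained
    erev_mV: -84.7            # subthreshold depolarization
    t_orig_C: 37.0
    density_S_per_cm2: {hillock: 0.0004, axon1: 0.0004, axon2: 0.0004, axon3: 0.0004, axon4: 0.0004}
    gates:
      - {name: w, form: inf_tau, exponent: 1,
         params: {vhalf: -66.0, k: 6.0, tau_min: 30.0, tau_amp: 0.0, vtau: -50.0, sigma: 20.0}}
  ka:                         # A-type K
    erev_mV: -84.7
    t_orig_C: 37.0
    density_S_per_cm2: {soma: 0.004}
    gates:
      - {name: a, form: inf_tau, exponent: 3,
         params: {vhalf: -42.0, k: 10.0, tau_min: 0.30, tau_amp: 1.5, vtau: -50.0, sigma: 18.0}}
      - {name: b, form: inf_tau, exponent: 1,
         params: {vhalf: -73.0, k: -8.0, tau_min: 5.0, tau_amp: 15.0, vtau: -70.0, sigma: 15.0}}
  kir:                        # inward rectifier K; baseline already carries the
    erev_mV: -84.7            # 1.5x in-vivo adaptation (1350 uS/cm2)
    t_orig_C: 37.0
    density_S_per_cm2: {soma: 0.00135}
    gates:
      - {name: d, form: inf_tau, exponent: 1,
         params: {vhalf: -85.0, k: -10.0, tau_min: 1.0, tau_amp: 6.0, vtau: -80.0, sigma: 20.0}}
  ca_hva:                     # high-threshold Ca
    erev_mV: 129.3
    t_orig_C: 37.0
    density_S_per_cm2: {soma: 0.0008}
    ca_source: true
    gates:
      - {name: c, form: inf_tau, exponent: 2,
         params: {vhalf: -25.0, k: 6.0, tau_min: 0.3, tau_amp: 1.0, vtau: -30.0, sigma: 15.0}}
  kca:                        # Ca-activated K (AHP)
    erev_mV: -84.7
    t_orig_C: 37.0
    density_S_per_cm2: {soma: 0.006}
    ca_gate: {kd_mM: 0.003, tau_ms: 1.0, exponent: 1}
  gaba_leak:                  # GABA-A leak; baseline carries the 2x in-vivo
    erev_mV: -65.0            # adaptation (60 uS/cm2)
    t_orig_C: 37.0
    density_S_per_cm2: {soma: 0.00006, dend1: 0.00006, dend2: 0.00006, dend3: 0.00006, dend4: 0.00006}
  leak:                       # ohmic leak; reversal adjusted at build time so
    erev_mV: -70.0            # the cell rests at resting_potential_mV
    t_orig_C: 37.0
    adjust_erev_for_rest: true
    density_S_per_cm2: {soma: 0.00015, dend1: 0.00015, dend2: 0.00015, dend3: 0.00015,
                        dend4: 0.00015, hillock: 0.00015, axon1: 0.00015, axon2: 0.00015,
                        axon3: 0.00015, axon4: 0.00015}

ca_pool:                      # submembrane shell feeding the KCa gate
  shell_depth_um: 0.2
  ca_rest_mM: 0.0001
  tau_ms: 1.5
  t_orig_C: 37.0
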