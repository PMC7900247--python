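# Synapse classes of the reduced granular-layer circuit.
#
# Each synapse couples a vesicle-cycling presynaptic model (release
# probability p, recovery tau_rec, facilitation tau_facil, inactivation
# tau_i), a two-component transmitter time course (1-ms cleft pulse plus a
# slow glomerular spillover exponential) and one or more multi-state receptor
# schemes.  Receptor ``weight_nS`` is the maximal open-state conductance
# contributed by one synaptic contact.  ``input`` weights mix the direct and
# spillover transmitter components seen by that receptor population.
#
# Units: mM, ms, nS, mV.
schema_version: 1
transmission_delay_ms: 1.0   # identical for every synapse class

synapses:
  mf_grc:                       # mossy fiber -> granule cell (AMPA + NMDA)
    transmitter: glutamate
    target: dendrite
    presyn: {p: 0.6, tau_rec_ms: 8.0, tau_facil_ms: 5.0, tau_i_ms: 1.0}
    timecourse: {direct_peak_mM: 1.0, direct_width_ms: 1.0, rel_ref: 0.6,
                 spill_peak_mM: 0.20, spill_tau_ms: 6.0, t_orig_C: 37.0}
    receptors:
      ampa:
        scheme: ampa
        weight_nS: 0.12
        erev_mV: 0.0
        input: {direct: 1.0, spillover: 0.4}
        closing_rate_scale: 1.0
        desens_recovery_scale: 1.0
      nmda:
        scheme: nmda
        weight_nS: 1.05
        erev_mV: 0.0
        mg_mM: 1.2
        input: {direct: 1.0, spillover: 0.15}
        closing_rate_scale: 1.0
        desens_recovery_scale: 1.0

  mf_goc:                       # mossy fiber -> Golgi cell (AMPA + NMDA)
    transmitter: glutamate      # weights calibrated to a -66 pA single-pulse
    target: soma                # EPSC at -70 mV holding
    presyn: {p: 0.6, tau_rec_ms: 8.0, tau_facil_ms: 5.0, tau_i_ms: 1.0}
    timecourse: {direct_peak_mM: 1.0, direct_width_ms: 1.0, rel_ref: 0.6,
                 spill_peak_mM: 0.20, spill_tau_ms: 6.0, t_orig_C: 37.0}
    receptors:
      ampa:
        scheme: ampa
        weight_nS: 1.94
        erev_mV: 0.0
        input: {direct: 1.0, spillover: 0.4}
        closing_rate_scale: 1.0
        desens_recovery_scale: 1.0
      nmda:
        scheme: nmda
        weight_nS: 30.0
        erev_mV: 0.0
        mg_mM: 1.2
        input: {direct: 1.0, spillover: 0.6}
        closing_rate_scale: 1.0
        desens_recovery_scale: 1.0

  pf_goc:                       # parallel fiber -> Golgi cell apical dendrite
    transmitter: glutamate      # (AMPA + NMDA + kainate)
    target: soma
    presyn: {p: 0.1, tau_rec_ms: 8.0, tau_facil_ms: 5.0, tau_i_ms: 1.0}
    timecourse: {direct_peak_mM: 1.0, direct_width_ms: 1.0, rel_ref: 0.1,
                 spill_peak_mM: 0.20, spill_tau_ms: 6.0, t_orig_C: 37.0}
    receptors:
      ampa:
        scheme: ampa
        weight_nS: 1.0
        erev_mV: 0.0
        input: {direct: 1.0, spillover: 0.4}
        closing_rate_scale: 1.0
        desens_recovery_scale: 1.0
      nmda:
        scheme: nmda
        weight_nS: 15.0
        erev_mV: 0.0
        mg_mM: 1.2
        input: {direct: 1.0, spillover: 0.6}
        closing_rate_scale: 1.0
        desens_recovery_scale: 1.0
      kainate:                  # AMPA scheme with slowed recovery from
        scheme: ampa            # desensitization (slow temporal summation)
        weight_nS: 0.4
        erev_mV: 0.0
        input: {direct: 1.0, spillover: 0.6}
        closing_rate_scale: 1.0
        desens_recovery_scale: 0.1

  aa_goc:                       # granule-cell ascending axon -> Golgi cell
    transmitter: glutamate      # basolateral dendrite (AMPA + NMDA, ~2x the
    target: soma                # parallel-fiber conductances)
    presyn: {p: 0.6, tau_rec_ms: 8.0, tau_facil_ms: 5.0, tau_i_ms: 1.0}
    timecourse: {direct_peak_mM: 1.0, direct_width_ms: 1.0, rel_ref: 0.6,
                 spill_peak_mM: 0.20, spill_tau_ms: 6.0, t_orig_C: 37.0}
    receptors:
      ampa:
        scheme: ampa
        weight_nS: 2.0
        erev_mV: 0.0
        input: {direct: 1.0, spillover: 0.4}
        closing_rate_scale: 1.0
        desens_recovery_scale: 1.0
      nmda:
        scheme: nmda
        weight_nS: 30.0
        erev_mV: 0.0
        mg_mM: 1.2
        input: {direct: 1.0, spillover: 0.6}
        closing_rate_scale: 1.0
        desens_recovery_scale: 1.0

  goc_grc:                      # Golgi cell -> granule cell (GABA-A alpha1 +
    transmitter: gaba           # alpha6 with glomerular spillover)
    target: dendrite
    presyn: {p: 0.35, tau_rec_ms: 36.0, tau_facil_ms: 58.5, tau_i_ms: 0.1}
    timecourse: {direct_peak_mM: 0.60, direct_width_ms: 1.0, rel_ref: 0.35,
                 spill_peak_mM: 0.05, spill_tau_ms: 30.0, t_orig_C: 37.0}
    receptors:
      gabaa_a1:                 # fast synaptic receptor
        scheme: gabaa_a1
        weight_nS: 1.5
        erev_mV: -65.0
        input: {direct: 1.0, spillover: 0.05}
        closing_rate_scale: 1.0
        desens_recovery_scale: 1.0
      gabaa_a6:                 # slow high-affinity receptor, spillover-driven
        scheme: gabaa_a6
        weight_nS: 0.015
        erev_mV: -65.0
        input: {direct: 0.1, spillover: 1.0}
        closing_rate_scale: 1.0
        desens_recovery_scale: 1.0

# Multi-state receptor kinetic schemes.  Transitions are first-order rates
# (1/ms); rates flagged ``ligand: true`` multiply the transmitter
# concentration (1/ms/mM).  Columns of the generator matrix conserve state
# occupancy by construction.  ``closing`` marks rates scaled by a synapse's
# closing_rate_scale; ``recovery`` marks desensitization-recovery rates scaled
# by desens_recovery_scale.
receptor_schemes:
  ampa:
    t_orig_C: 37.0
    states: [C0, C1, C2, O, D]
    open_states: [O]
    transitions:
      - {from: C0, to: C1, rate: 4.0, ligand: true}
      - {from: C1, to: C0, rate: 2.0}
      - {from: C1, to: C2, rate: 8.0, ligand: true}
      - {from: C2, to: C1, rate: 4.0}
      - {from: C2, to: O, rate: 20.0}
      - {from: O, to: C2, rate: 4.0, closing: true}
      - {from: C2, to: D, rate: 1.8}
      - {from: D, to: C2, rate: 0.05, recovery: true}
  nmda:
    t_orig_C: 37.0
    states: [C0, C1, C2, O, D]
    open_states: [O]
    transitions:
      - {from: C0, to: C1, rate: 1.2, ligand: true}
      - {from: C1, to: C0, rate: 0.22}
      - {from: C1, to: C2, rate: 2.4, ligand: true}
      - {from: C2, to: C1, rate: 0.44}
      - {from: C2, to: O, rate: 0.30}
      - {from: O, to: C2, rate: 0.15, closing: true}
      - {from: C2, to: D, rate: 0.02}
      - {from: D, to: C2, rate: 0.003, recovery: true}
  gabaa_a1:
    t_orig_C: 37.0
    states: [C0, C1, C2, O, D]
    open_states: [O]
    transitions:
      - {from: C0, to: C1, rate: 2.0, ligand: true}
      - {from: C1, to: C0, rate: 2.0}
      - {from: C1, to: C2, rate: 4.0, ligand: true}
      - {from: C2, to: C1, rate: 4.0}
      - {from: C2, to: O, rate: 8.0}
      - {from: O, to: C2, rate: 0.30, closing: true}
      - {from: C2, to: D, rate: 1.5}
      - {from: D, to: C2, rate: 0.02, recovery: true}
  gabaa_a6:
    t_orig_C: 37.0
    states: [C0, C1, O, D]
    open_states: [O]
    transitions:
      - {from: C0, to: C1, rate: 15.0, ligand: true}
      - {from: C1, to: C0, rate: 0.12}
      - {from: C1, to: O, rate: 1.2}
      - {from: O, to: C1, rate: 0.10, closing: true}
      - {from: C1, to: D, rate: 0.25}
      - {from: D, to: C1, rate: 0.02, recovery: true}

# Jahr–Stevens-type voltage-dependent Mg block of the NMDA receptor:
# B(V) = 1 / (1 + [Mg]/K * exp(-V/v0)).  Mg-free protocols set [Mg] = 0.
mg_block: {k_mM: 3.57, v0_mV: 16.13}
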