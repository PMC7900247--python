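# Golgi cell, reduced single-compartment spiking model.
#
# The circuit protocols only consume the Golgi cell's spike timing (it is the
# presynaptic source of feedforward inhibition), so the cell is represented by
# a compact Na/K/leak compartment tuned to rest near -60 mV and to relay a
# mossy-fiber EPSC into a spike within a few milliseconds.
schema_version: 1
cell: goc
resting_potential_mV: -60.0
capacitance_uF_per_cm2: 1.0
axial_resistivity_ohm_cm: 100.0

compartments:
  - {name: soma, role: soma, parent: null, length_um: 12.0, diameter_um: 12.0}

channels:
  na_t:
    erev_mV: 87.4
    t_orig_C: 37.0
    density_S_per_cm2: {soma: 0.04}
    gates:
      - {name: m, form: inf_tau, exponent: 3,
         params: {vhalf: -44.0, k: 5.0, tau_min: 0.03, tau_amp: 0.20, vtau: -42.0, sigma: 18.0}}
      - {name: h, form: inf_tau, exponent: 1,
         params: {vhalf: -52.0, k: -6.0, tau_min: 0.25, tau_amp: 7.0, vtau: -55.0, sigma: 12.0}}
  kv:
    erev_mV: -84.7
    t_orig_C: 37.0
    density_S_per_cm2: {soma: 0.02}
    gates:
      - {name: n, form: inf_tau, exponent: 4,
         params: {vhalf: -40.0, k: 8.0, tau_min: 0.40, tau_amp: 5.0, vtau: -50.0, sigma: 20.0}}
  leak:
    erev_mV: -60.0
    t_orig_C: 37.0
    adjust_erev_for_rest: true
    density_S_per_cm2: {soma: 0.00025}
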