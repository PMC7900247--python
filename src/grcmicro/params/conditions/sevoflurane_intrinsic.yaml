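# Anesthetic condition, full intrinsic bundle: persistent-Na kinetic
# acceleration plus increased Na conductance (0.03 -> 0.04 S/cm2 hillock,
# 0.02 -> 0.03 axon) and increased delayed-rectifier K conductance
# (0.003 -> 0.005 S/cm2, hillock and axon).  No synaptic changes.
name: sevoflurane_intrinsic
notes: Intrinsic-excitability bundle only (Nap kinetics + Na and Kv densities).
intrinsic:
  grc:
    channels.na_p.kinetics.a_on: 1.5
    channels.na_p.kinetics.a_off: 0.05
    channels.na_t.density_S_per_cm2.hillock: 0.04
    channels.na_t.density_S_per_cm2.axon1: 0.03
    channels.na_t.density_S_per_cm2.axon2: 0.03
    channels.na_t.density_S_per_cm2.axon3: 0.03
    channels.na_t.density_S_per_cm2.axon4: 0.03
    channels.kv.density_S_per_cm2.hillock: 0.005
    channels.kv.density_S_per_cm2.axon1: 0.005
    channels.kv.density_S_per_cm2.axon2: 0.005
    channels.kv.density_S_per_cm2.axon3: 0.005
    channels.kv.density_S_per_cm2.axon4: 0.005
synaptic: {}
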