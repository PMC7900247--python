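# Anesthetic condition, persistent-Na kinetics component only:
# activation/deactivation scales accelerated (0.75 -> 1.5, 0.005 -> 0.05).
# Used to dissect which intrinsic change drives the firing-rate saturation.
name: sevoflurane_nap
notes: Persistent-Na kinetic acceleration only (no Na/K density change, no synaptic change).
intrinsic:
  grc:
    channels.na_p.kinetics.a_on: 1.5
    channels.na_p.kinetics.a_off: 0.05
synaptic: {}
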