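# Full anesthetic condition bundle.
#
# Intrinsic: persistent-Na kinetic acceleration plus Na/Kv density increases.
# Synaptic: NMDA conductance removed at the excitatory mossy-fiber inputs to
# the granule cell; GABAergic GoC->GrC synapse potentiated pre- and
# post-synaptically.  The four GABA scale values (release probability, alpha1
# closing rate, alpha6 spillover-receptor weight, glomerular spillover decay)
# were calibrated once against the experimentally measured percent changes of
# evoked IPSC peak (+47.6 +/- 7.1 %), decay tau (+43.8 +/- 6.5 %) and
# paired-pulse ratio (-12.7 +/- 2.3 %), then frozen here.
name: sevoflurane
notes: Full bundle (intrinsic + synaptic); GABA values calibrated, see docs/methods.md.
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
synaptic:
  mf_grc:
    receptors.nmda.weight_nS: 0.0
  goc_grc:
    presyn.p: 0.4448
    receptors.gabaa_a1.closing_rate_scale: 0.90
    receptors.gabaa_a6.weight_nS: 0.0375
    timecourse.spill_tau_ms: 120.0
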