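# Baseline condition: the identity bundle (no overrides).
name: control
notes: Baseline granular-layer model; every other condition is a diff against this.
intrinsic: {}
synaptic: {}
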