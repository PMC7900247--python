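# grcmicro

A conductance-based model of the cerebellar granular-layer input stage —
one granule cell (GrC) driven by 1–4 mossy fibers and inhibited by 0–7
Golgi cells (GoC) — built to compare a *control* parameter bundle against a
*sevoflurane* bundle that encodes the anesthetic's cellular actions as
explicit, auditable parameter changes.

## The scientific problem

Sevoflurane reshapes neurotransmission at the cerebellar input stage in
three ways that a biophysical model can dissect quantitatively:

1. **Intrinsic excitability.** The persistent Na⁺ current (I_NaP) sets the
   firing threshold of the high-resistance GrC.  The anesthetic bundle
   changes its kinetic time scales (A_on 0.75 → 1.5 ms, A_off
   0.005 → 0.05 ms), which shifts the activation midpoint by
   k·ln(A_off′/A_off ÷ A_on′/A_on) ≈ 8 mV toward hyperpolarized potentials,
   lowering the repetitive-firing threshold from ≈ −47 to ≈ −55 mV.  The
   overall Na conductance rises (0.03 → 0.04 S/cm² hillock, 0.02 → 0.03
   axon) and the delayed-rectifier K conductance rises (0.003 → 0.005
   S/cm²), which lifts the spike-count difference beyond the saturation the
   Nap change alone produces.
2. **GABAergic potentiation.** The GoC→GrC synapse combines
   Tsodyks–Markram vesicle cycling (p = 0.35, τ_rec = 36 ms, τ_facil =
   58.5 ms, τ_I = 0.1 ms) with fast α1 and slow spillover-driven α6 GABA-A
   receptor schemes.  Four calibrated scale values (release probability, α1
   closing rate, α6 weight, glomerular spillover decay) reproduce the
   measured evoked-IPSC changes; the frozen bundle then *predicts* the
   single-stimulus IPSC peak and charge changes.
3. **NMDA block.** The excitatory mf→GrC synapse (p = 0.6, τ_rec = 8 ms)
   loses its NMDA conductance entirely under the anesthetic bundle, while
   AMPA is untouched.

Everything is organized as parameter files plus condition bundles: the
control files are the baseline, and each condition is a key-by-key diff.

## Worked example

Reproduce the single-stimulus inhibitory-synapse comparison (the
voltage-clamped GrC receives one GoC stimulus under both bundles):

```python
from grcmicro.reproduce import reproduce
rep = reproduce("fig8a")
print(rep.table())
```

prints

```
check                                           value     target      tol  pass
IPSC peak change (%)                            48.09      46.30     6.94    ok
IPSC charge change (%)                          93.76      99.60    14.94    ok
```

i.e. the frozen anesthetic bundle increases the simulated IPSC peak by
≈ 48 % and the transferred charge by ≈ 94 %, within the documented
tolerance of the study values it reproduces (+46.3 % and +99.6 %).

Lower-level building blocks are regular library calls:

```python
from grcmicro import (Circuit, CircuitSpec, build_grc, integrate, Stimulus,
                      run_current_steps, intrinsic_summary)

cell = build_grc("sevoflurane_nap", temperature=30.0)   # Nap kinetics only
trace = integrate(cell, Stimulus.step(6.0, 50.0, 450.0), duration=500.0)

summary = intrinsic_summary(run_current_steps("control", 1, 16, duration=400.0))
print(summary["threshold_mV"])   # ≈ -48.1 (repetitive-discharge threshold)
```

A thin CLI mirrors the library (`grcmicro simulate|sweep|analyze|synth|reproduce`).

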