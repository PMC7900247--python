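# Methods

## Scope and model overview

`grcmicro` models the input stage of the cerebellar cortex — one granule
cell (GrC) driven by 1–4 mossy fibers (mf) and inhibited by 0–7 Golgi cells
(GoC) — well enough to compare a *control* parameter bundle against a
*sevoflurane* bundle in which the anesthetic's cellular actions are encoded
as explicit parameter changes:

* intrinsic: the persistent-Na (Nap) kinetic time scales accelerate
  (`A_on` 0.75 → 1.5 ms, `A_off` 0.005 → 0.05 ms), the transient-Na density
  rises (0.03 → 0.04 S/cm² hillock, 0.02 → 0.03 S/cm² axon) and the
  delayed-rectifier K density rises (0.003 → 0.005 S/cm²);
* synaptic: the NMDA conductance of the excitatory mf→GrC input is removed,
  and the GABAergic GoC→GrC synapse is potentiated pre- and postsynaptically
  (four calibrated scale values, see below).

Every deviation from control lives in a YAML condition file as an explicit
key-by-key diff, so the bundles are auditable and any subset (for example
the Nap-kinetics change alone) is itself a registered condition.

## Granule-cell model

The GrC is a compartmental conductance-based model: soma, four short
dendrites, axon hillock, and a tapered ascending axon resolved as four
50-µm segments (diameters 0.4, 0.3, 0.2, 0.2 µm).  The taper matters: the
persistent Na lives only in the two thin distal segments, which are weakly
coupled to each other (≈0.6 nS) so the spike ignites distally at a fold set
by the persistent-Na window; the thick proximal segment couples strongly to
the soma, so the invading axonal spike — not a local somatic current — is
what drives the somatic dV/dt through the detection criterion.  This
separation is what lets a small persistent current set the measured
threshold while every condition still holds a quiet −60 mV under bias.

Channels: transient Na (m³h), persistent Na (m with slow inactivation s),
delayed-rectifier K (n⁴), slow M-type K (w), A-type K (a³b), inward
rectifier K, high-threshold Ca (c²) with a submembrane Ca pool, Ca-activated
K, a GABA-A leak (60 µS/cm², the doubled in-vivo adaptation of the base
model) and an ohmic leak.  The inward-rectifier density is 1350 µS/cm² (the
1.5× in-vivo adaptation).  Rate equations for the base conductances are not
printed in the source study (they come from the cited granule-cell and
Golgi-cell model lineage), so they are encoded here as Boltzmann
steady-state/time-constant or exponential-rate forms in versioned parameter
files and calibrated once against the study's *printed simulation outputs*
(resting potential −70 mV, firing threshold −47 mV in control, −54.8 mV
under the Nap change, rheobase ordering).  The parameter files are the
ground truth of the model; nothing numerical is hard-coded.

### Persistent-Na kinetics and the anesthetic threshold shift

`A_on` and `A_off` enter as the characteristic time scales of the
activation/deactivation rate expressions: the forward rate is proportional
to `1/A_on` and the backward rate to `1/A_off` (both carry ms units).  The
activation midpoint of the gate therefore sits at
`v0 + k·ln(b_mag·A_on / (a_mag·A_off))`: when the anesthetic multiplies
`A_off` by ten but `A_on` only by two, the midpoint shifts
`k·ln(5) ≈ 8 mV` toward hyperpolarized potentials and the deactivation
slows.  The persistent current then becomes regenerative around −55 mV
instead of −47 mV, which is precisely the printed threshold change.  (Read
as pure rate multipliers the same numbers would shift activation the other
way and *raise* the threshold, contradicting the reproduced outputs; the
time-scale reading is also the one consistent with the printed ms units.)

The slow inactivation gate s (midpoint −63 mV, slope −2.5 mV, τ ≈ 130 ms
at 30 °C) and the slow M-type K current bound the window current: sustained
depolarization prunes the Nap window, which (i) lets every condition hold a
−60 mV membrane potential stably after an accommodation transient, and
(ii) produces the saturation of the spike-count difference at strong drive
that distinguishes the Nap-only bundle from the full intrinsic bundle.

### Threshold measurement

Spike threshold is the membrane potential at which somatic dV/dt first
exceeds 20 mV/ms on the upstroke (documented, configurable constant), with
sub-sample interpolation of the crossing so the estimate converges under
dt-halving.  Step protocols run from the model's rest (−70 mV) with 400-ms
steps in 1-pA increments; the reported threshold is read from the first
spike at the lowest amplitude that evokes repetitive firing (≥ 2 spikes),
matching how the threshold of repetitive discharges is quoted.  Protocols
that require a depolarized baseline (EPSPs, paired-pulse sweeps) hold the
soma near −60 mV with a bias current found by settle simulations — the
uniform steady-state estimate is refined against the simulated settled
potential, because slow gates and axial gradients shift the true operating
point; accommodation spikes during the settle window precede every
measurement window.

## Temperature

All rates are defined at the base-model reference temperature (37 °C after
the in-vivo adaptation) and rescaled to the 30 °C simulation temperature
with `Q10^((T_sim−T_orig)/10)`: Q10 = 3 for channel gating and Ca
pumps/buffers, 2.4 for receptor gating, 1.5 for permeation (scales maximal
conductances), 1.3 for transmitter diffusion, and 1.3 (GrC) / 1.7 (GoC) for
intracellular Ca diffusion.  The source Methods print the correction as a
difference quotient; that form would give a factor of zero at equal
temperatures, so it is treated as shorthand for the standard exponential
law.  The Methods also list the Ca-diffusion Q10 as "1.3 (GrC) or 1.7
(GrC)" — the second entry is recorded in the parameter files as the GoC
value, flagged as a presumed typo.

## Golgi cell

The circuit consumes only the GoC's spike timing (it is the feedforward
inhibitory relay), so the GoC is a reduced single-compartment Na/K/leak
model resting near −60 mV that relays a mossy-fiber EPSC into a spike
within a few milliseconds.  This is a deliberate simplification of the full
multicompartment GoC of the model lineage; the mf→GoC synapse is calibrated
to the printed −66 pA single-pulse EPSC (holding −70 mV assumed, as the
holding potential for that calibration is not stated).  All GoCs in a
circuit are identical and see identical drive, so one GoC simulation serves
any GoC count.

## Synapses

Each synapse class couples three stages:

1. **Vesicle cycling** (Tsodyks–Markram family): a three-state pool
   (recovered x, effective y, inactive z; closed-form inter-spike
   relaxation, conservation to machine precision) with facilitation u.  At
   a spike u jumps by `U·(1−u)` *before* release and the released fraction
   is `u·x`; with baseline `U = p` the first release of a resting train is
   exactly p.  Parameters as printed: mf→GrC p = 0.6, τ_rec = 8 ms,
   τ_facil = 5 ms, τ_I = 1 ms; GoC→GrC p = 0.35, τ_rec = 36 ms,
   τ_facil = 58.5 ms, τ_I = 0.1 ms; PF→GoC p = 0.1; AA→GoC as mf→GrC with
   ≈2× the PF→GoC conductances.  Transmission delay is 1 ms everywhere.
2. **Transmitter time course**: a 1-ms cleft pulse plus a slow glomerular
   spillover exponential, both scaling linearly with the released fraction
   relative to the class's resting release probability.  The spillover
   decay carries the diffusion Q10.
3. **Receptor schemes**: first-order kinetic schemes over closed, open and
   desensitized states (AMPA, NMDA, GABA-A α1, GABA-A α6, kainate = AMPA
   with 10× slowed desensitization recovery).  Occupancies evolve under a
   conservative generator integrated with backward Euler, so total
   occupancy is conserved exactly.  The NMDA current is multiplied by a
   two-parameter sigmoidal Mg block, `1/(1 + [Mg]/3.57·exp(−V/16.13))`,
   with [Mg] an explicit protocol parameter (Mg-free protocols set 0
   exactly).  Rate constants are not printed in the source; they are
   encoded in the parameter file with kinetics in the range reported for
   these receptor families and frozen.

Quantal/stochastic release is deliberately absent from production runs; a
binomial Monte-Carlo release simulation exists purely as the test oracle
for the deterministic recursion.

### The sevoflurane GABA bundle

The supplementary table holding the study's GABA-synapse values is not
reproduced in the available text, so the bundle is implemented as four free
scale values — release probability, α1 closing rate, α6 (spillover-pathway)
weight, and glomerular spillover decay — calibrated once against the
experimentally measured percent changes of the evoked IPSC (peak
+47.6 ± 7.1 %, decay τ +43.8 ± 6.5 %, paired-pulse ratio −12.7 ± 2.3 %) and
then frozen in the condition file (p 0.35 → 0.4448, α1 closing ×0.90, α6
weight 0.015 → 0.0375 nS, spillover τ 30 → 120 ms).  The single-stimulus IPSC
percent changes of the simulated figure (+46.3 % peak, +99.6 % charge) are
*outputs* of the frozen bundle, not calibration inputs.

## Protocols and metrics

Protocols mirror the experimental designs: voltage-clamped EPSC bursts
(4 × 100 Hz at −70 mV), pharmacological NMDA isolation (−40 mV, Mg-free,
AMPA/GABA blocked), evoked IPSCs with excitation blocked (single pulses or
pairs at 50 Hz), subthreshold EPSPs from −60 mV with and without
feedforward inhibition, and paired-pulse frequency sweeps (10–200 Hz)
across the excitation/inhibition grid.  Stimulation intensity is a protocol
parameter (``mf_scale``), mirroring experimental practice: the spiking
sweep protocols use a suprathreshold intensity (3.2× the nominal
mossy-fiber drive) while EPSP protocols use deliberately weak stimuli so
responses stay subthreshold in every condition.  Voltage clamp is ideal whole-cell
clamp (every compartment held), appropriate for this electrotonically
compact cell; clamp current is the total membrane current, outward
positive.

Metrics follow the experimental definitions: peak amplitude, time to peak,
10–90 % rise time, mono-exponential decay fit from the event peak to
baseline return (5 % of peak) or the next stimulus, total charge as the
unsigned integral from stimulus onset, paired-pulse ratio as second/first
peak, EPSP total depolarization as the integral over the fixed
[onset, onset + 50 ms] window, spike AHP as threshold minus the post-spike
minimum, half-width at 50 % of (peak − threshold), and the output frequency
of doublet responses as spikes per fixed 100-ms response window (the window
is a documented choice; the source does not define one).  Instantaneous
frequency is reported both as first-ISI⁻¹ and mean-ISI⁻¹ since the summary
convention is not defined in the source.  Baselines are means over the
20 ms preceding the first stimulus; EPSP/PSC onsets subtract the 1-ms
synaptic delay.  Condition comparisons report percent change
(100·(treated−control)/|control|), mean ± SEM and a paired two-sided
Student's t.

## Numerics

Fixed-step integration at dt = 0.025 ms: gating variables relax exactly
toward tabulated steady states (voltage grid −120…80 mV, 0.05 mV,
linear interpolation), and the coupled compartment voltages advance with an
implicit theta rule (θ = 0.5) staggered against the gate update.  dt-halving
convergence (identical spike counts, spike-time shifts < 0.1 ms, threshold
shifts < 0.3 mV) is asserted in the test suite.  Receptor occupancies use
backward Euler, which conserves total occupancy identically.  The Ca pool
is explicit Euler with a floor at 1 nM.  All simulations are deterministic;
the only randomness in the package lives in the synthetic-trace generators
and the Monte-Carlo release oracle, both pure functions of (spec, seed)
with seeds fanned out from one global seed by a documented splitting rule.

## Synthetic fixtures: what they do and do not show

The synthetic generators emulate patch-clamp-like traces — biexponential
PSC trains with white Gaussian noise at known event times (kernel defaults
echo the recorded kinetics: 10–90 % rise ≈ 1.4 ms, decay ≈ 18 ms,
spontaneous rate 3.1 Hz) and spike trains with constructed threshold
crossings.  They validate the analysis operators against closed forms, not
the biophysics: passing those tests shows the *metrics* are correct, not
that the cell model reproduces real recordings.  Realistic recording
artifacts (line noise, series-resistance transients, electrode drift) are
deliberately not modeled, so operator robustness to such artifacts is
untested.

## Known limitations

* Base-model fidelity: channel and receptor rate equations are re-encoded,
  not copied from the cited models; only the printed simulation outputs
  constrain them.  Quantities the source does not print (absolute EPSC
  amplitudes at the GrC, f-I gain) can deviate from the original model.
* The resurgent Na component of the base model is not separated out; the
  printed Na-density changes scale a single transient + persistent pair.
* The GoC is a spiking relay, not a full multicompartment model; GoC-level
  phenomena (pacemaking, sub/suprathreshold resonance) are out of scope.
* The GrC→GoC feedback loop exists in the wiring but is off by default in
  the reduced protocols (the simulated figures only need feedforward
  inhibition).
* Ideal whole-cell voltage clamp ignores series-resistance and space-clamp
  errors deliberately.
* At strong sustained drive the accommodating gates bound the absolute
  spike-count difference between conditions; the reproduced orderings hold
  but the difference magnitudes saturate earlier than in the experimental
  f-I curves.
* The NMDA scheme is encoded with fast, unbinding-limited deactivation
  (≈10 ms at 30 °C).  This is what makes the no-inhibition EPSP
  percent-change pair land, but it shortens the temporal summation of the
  pharmacologically isolated current: its peak follows the last stimulus by
  only a few milliseconds rather than the ~20 ms seen experimentally.
* The calibrated anesthetic bundle's intrinsic fold sits ~6 mV below
  control, which makes the anesthetic EPSP peak nearly inhibition-proof:
  the simulated with-inhibition EPSP peak change plateaus near −8 % (the
  study's model prints −32.4 %) while the doubled inhibitory charge
  overshoots the 50-ms area change.  Likewise, the anesthetic condition's
  early axonal spike in the paired-pulse sweep resists feedforward
  inhibition, so the total-spike reduction at every inhibited
  configuration is not reproduced even though the delay orderings and the
  input–output slope reduction are.  Both mismatches trade directly
  against the threshold calibration and are documented rather than tuned
  away.
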