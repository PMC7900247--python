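"""Reduced granular-layer microcircuit and stimulation protocols.

The circuit couples one granule cell to 1–4 mossy fibers and 0–7 Golgi
cells.  Mossy fibers are ideal spike sources at the commanded pulse times;
each drives the granule cell (AMPA + NMDA) and the Golgi cells (mf→GoC
synapse), so inhibition arrives feedforward with one synaptic delay per hop.
Golgi-cell spiking is simulated with the reduced GoC model; identical GoCs
receive identical drive, so one GoC simulation serves all of them.

Protocols mirror the experimental designs: current-step series for intrinsic
excitability, voltage-clamped EPSC bursts, pharmacologically isolated NMDA
and IPSC recordings, paired-pulse frequency sweeps and subthreshold EPSPs.
Pharmacological flags (``ampa_off``, ``nmda_off``, ``gaba_off``, ``mg_free``)
emulate the blockers used experimentally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import detect_spikes, spike_metrics
from .cell import CellModel, build_goc, build_grc
from .conditions import ConditionSet, ConfigurationError, get_condition
from .simulate import (CURRENT_CLAMP, VOLTAGE_CLAMP, Stimulus, SynapticInput,
                       integrate)
from .synapse import build_synapse, synapse_conductances
from .trace import Trace

DT_DEFAULT = 0.025


@dataclass
class CircuitSpec:
    """Wiring of the reduced circuit."""

    n_mf: int = 1
    n_goc: int = 0
    feedback: bool = False   # GrC->GoC feedback loop (off for reduced runs)

    def __post_init__(self) -> None:
        if not 1 <= self.n_mf <= 4:
            raise ValueError(f"n_mf must be in 1..4, got {self.n_mf}")
        if not 0 <= self.n_goc <= 7:
            raise ValueError(f"n_goc must be in 0..7, got {self.n_goc}")


@dataclass
class Protocol:
    """A stimulation/recording protocol description."""

    id: str
    mode: str                      # current-clamp | voltage-clamp
    holding_mV: float | None = None
    pulse_times_ms: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    duration_ms: float = 300.0
    dt_ms: float = DT_DEFAULT
    repeats: int = 1
    seed: int | None = None


@dataclass
class ProtocolResult:
    """Traces plus metadata produced by one protocol run."""

    protocol: Protocol
    condition: str
    traces: list
    extras: dict = field(default_factory=dict)

    @property
    def trace(self) -> Trace:
        return self.traces[0]


def _receptor_filter(flags: dict):
    off = set()
    if flags.get("ampa_off"):
        off |= {"ampa", "kainate"}
    if flags.get("nmda_off"):
        off.add("nmda")
    if flags.get("gaba_off"):
        off |= {"gabaa_a1", "gabaa_a6"}
    if not off:
        return None
    return lambda name: name not in off


class Circuit:
    """An assembled GrC + mossy fiber + Golgi cell circuit under a condition."""

    def __init__(self, spec: CircuitSpec, condition: str | ConditionSet = "control",
                 temperature: float = 30.0, dt: float = DT_DEFAULT):
        self.spec = spec
        self.condition = get_condition(condition) if isinstance(condition, str) else condition
        self.temperature = temperature
        self.dt = dt
        self.grc = build_grc(self.condition, temperature)
        self.goc = build_goc(self.condition, temperature) if spec.n_goc > 0 else None
        self.syn_mf_grc = build_synapse("mf_grc", self.condition, temperature)
        self.syn_mf_goc = build_synapse("mf_goc", self.condition, temperature)
        self.syn_goc_grc = build_synapse("goc_grc", self.condition, temperature)
        self._bias_cache: dict = {}

    # ------------------------------------------------------------ helpers

    def _dend_index(self, i: int) -> int:
        dends = [k for k, c in enumerate(self.grc.compartments) if c.role == "dendrite"]
        return dends[i % len(dends)]

    def goc_spike_times(self, mf_times, duration: float, flags: dict | None = None
                        ) -> np.ndarray:
        """Spike times of one (representative) Golgi cell driven by the
        mossy fibers.  All GoCs are identical and see identical drive."""
        if self.goc is None:
            return np.array([])
        flags = flags or {}
        rf = _receptor_filter(flags)
        syn_inputs = []
        for _ in range(self.spec.n_mf):
            gs, _, _ = synapse_conductances(self.syn_mf_goc, mf_times, duration,
                                            self.dt, receptor_filter=rf)
            for c in gs:
                syn_inputs.append(SynapticInput(comp=0, g_nS=c.g_nS,
                                                erev_mV=c.erev_mV, block=c.block()))
        tr = integrate(self.goc, Stimulus.zero(), duration=duration, dt=self.dt,
                       syn_inputs=syn_inputs)
        return detect_spikes(tr)

    def grc_synaptic_inputs(self, mf_times, duration: float,
                            flags: dict | None = None,
                            goc_times=None, mf_scale: float = 1.0) -> list:
        """Per-receptor synaptic conductances onto the granule cell.

        ``mf_scale`` models the stimulation intensity of the mossy-fiber
        electrode (suprathreshold protocols recruit stronger compound input
        than the deliberately weak stimuli used for subthreshold EPSPs).
        """
        flags = flags or {}
        rf = _receptor_filter(flags)
        mg_free = flags.get("mg_free", False)
        inputs = []
        mf_times = list(mf_times)
        if mf_times:
            for i in range(self.spec.n_mf):
                spec = self.syn_mf_grc
                gs, _, _ = synapse_conductances(spec, mf_times, duration, self.dt,
                                                receptor_filter=rf)
                for c in gs:
                    if mg_free:
                        c.mg_mM = 0.0
                    inputs.append(SynapticInput(
                        comp=self._dend_index(i), g_nS=mf_scale * c.g_nS,
                        erev_mV=c.erev_mV, block=c.block()))
        if self.spec.n_goc > 0 and not flags.get("gaba_off"):
            if goc_times is None:
                goc_times = self.goc_spike_times(mf_times, duration, flags)
            if len(goc_times):
                gs, _, _ = synapse_conductances(self.syn_goc_grc, goc_times,
                                                duration, self.dt,
                                                receptor_filter=rf)
                for j in range(self.spec.n_goc):
                    for c in gs:
                        inputs.append(SynapticInput(
                            comp=self._dend_index(j), g_nS=c.g_nS,
                            erev_mV=c.erev_mV, block=c.block()))
        return inputs

    def holding_bias(self, v_target: float, settle_ms: float = 400.0,
                     tol_mV: float = 0.5, max_iter: int = 5) -> float:
        """Bias current holding the (accommodated) soma at ``v_target``.

        Found by settle simulations: the uniform steady-state estimate is
        refined against the simulated settled potential, because slow gates
        and axial gradients shift the true operating point.
        """
        key = (self.condition.name, round(v_target, 2))
        if key in self._bias_cache:
            return self._bias_cache[key]
        bias = self.grc.holding_current_pA(v_target)
        g_est = 0.6  # nS, slope guess for the damped update
        best = (float("inf"), bias)
        for _ in range(max_iter):
            tr = integrate(self.grc, Stimulus.step(0.0, 0, 1, bias_pA=bias),
                           duration=settle_ms, dt=self.dt)
            v = float(np.mean(tr.data[-int(50.0 / self.dt):]))
            err = v_target - v
            if abs(err) < best[0]:
                best = (abs(err), bias)
            if abs(err) < tol_mV:
                break
            # damped: accommodation makes the settle curve non-monotone
            bias += 0.5 * err * g_est
        self._bias_cache[key] = best[1]
        return best[1]


# ------------------------------------------------------------------ protocols

def run_current_steps(condition: str | ConditionSet, step_min: float = 1.0,
                      step_max: float = 20.0, step: float = 1.0,
                      duration: float = 500.0, temperature: float = 30.0,
                      dt: float = DT_DEFAULT, onset: float = 50.0
                      ) -> ProtocolResult:
    """Voltage responses of the isolated GrC to a step-current series.

    Synaptic inputs are disabled (intrinsic protocol, the pharmacological
    analog of glutamatergic/GABAergic blockade).  One trace per amplitude.
    """
    amps = np.arange(step_min, step_max + step / 2, step)
    if amps.size == 0:
        raise ValueError("empty step range")
    cell = build_grc(condition, temperature)
    traces = []
    for a in amps:
        tr = integrate(cell, Stimulus.step(float(a), onset, onset + duration),
                       duration=duration + 100.0, dt=dt)
        tr.meta.update(amplitude_pA=float(a), onset_ms=onset, protocol="current_steps")
        traces.append(tr)
    proto = Protocol(id="current_steps", mode=CURRENT_CLAMP,
                     duration_ms=duration + 100.0, dt_ms=dt)
    cond_name = condition if isinstance(condition, str) else condition.name
    return ProtocolResult(proto, cond_name, traces,
                          extras={"amplitudes_pA": amps, "onset_ms": onset,
                                  "window_ms": duration})


def intrinsic_summary(result: ProtocolResult) -> dict:
    """Rheobase, repetitive-firing threshold and f-I curve from a step series.

    The firing threshold is read from the first spike of the lowest step that
    evokes repetitive firing (>= 2 spikes), matching how the threshold of
    repetitive discharges is reported experimentally.
    """
    onset = result.extras["onset_ms"]
    window = result.extras["window_ms"]
    counts, rheo, thr, thr_amp = [], None, float("nan"), None
    freqs = []
    for tr in result.traces:
        sm = spike_metrics(tr, stim_onset=onset, window_ms=window)
        counts.append(sm.count)
        freqs.append(sm.mean_frequency)
        if rheo is None and sm.count >= 1:
            rheo = tr.meta["amplitude_pA"]
        if thr_amp is None and sm.count >= 2:
            thr_amp = tr.meta["amplitude_pA"]
            thr = float(sm.thresholds[0])
    return {"amplitudes_pA": np.asarray(result.extras["amplitudes_pA"]),
            "spike_counts": np.asarray(counts),
            "mean_freq_hz": np.asarray(freqs),
            "rheobase_pA": rheo, "threshold_mV": thr,
            "threshold_step_pA": thr_amp}


def run_epsc_burst(circuit: Circuit, n_pulses: int = 4, freq_hz: float = 100.0,
                   holding: float = -70.0, onset: float = 50.0,
                   tail_ms: float = 100.0) -> ProtocolResult:
    """EPSC burst under voltage clamp (mossy-fiber train, GABA blocked
    chemically by the chloride driving force at the holding potential)."""
    isi = 1e3 / freq_hz
    pulses = [onset + k * isi for k in range(n_pulses)]
    duration = pulses[-1] + tail_ms
    flags = {"gaba_off": True}
    syn = circuit.grc_synaptic_inputs(pulses, duration, flags)
    tr = integrate(circuit.grc, None, duration=duration, dt=circuit.dt,
                   mode=VOLTAGE_CLAMP, holding=holding, syn_inputs=syn)
    tr.meta.update(protocol="epsc_burst", pulses_ms=pulses)
    proto = Protocol(id="epsc_burst", mode=VOLTAGE_CLAMP, holding_mV=holding,
                     pulse_times_ms=pulses, flags=flags, duration_ms=duration,
                     dt_ms=circuit.dt)
    return ProtocolResult(proto, circuit.condition.name, [tr],
                          extras={"pulses_ms": pulses})


def run_nmda_isolation(circuit: Circuit, n_pulses: int = 4,
                       freq_hz: float = 100.0, holding: float = -40.0,
                       onset: float = 50.0, tail_ms: float = 150.0
                       ) -> ProtocolResult:
    """Pharmacologically isolated NMDA current: AMPA and GABA receptors
    blocked, Mg removed, holding −40 mV."""
    isi = 1e3 / freq_hz
    pulses = [onset + k * isi for k in range(n_pulses)]
    duration = pulses[-1] + tail_ms
    flags = {"ampa_off": True, "gaba_off": True, "mg_free": True}
    syn = circuit.grc_synaptic_inputs(pulses, duration, flags)
    tr = integrate(circuit.grc, None, duration=duration, dt=circuit.dt,
                   mode=VOLTAGE_CLAMP, holding=holding, syn_inputs=syn)
    tr.meta.update(protocol="nmda_isolation", pulses_ms=pulses)
    proto = Protocol(id="nmda_isolation", mode=VOLTAGE_CLAMP, holding_mV=holding,
                     pulse_times_ms=pulses, flags=flags, duration_ms=duration,
                     dt_ms=circuit.dt)
    return ProtocolResult(proto, circuit.condition.name, [tr],
                          extras={"pulses_ms": pulses})


def run_ipsc_protocol(circuit: Circuit, n_pulses: int = 1, freq_hz: float = 50.0,
                      holding: float = -60.0, onset: float = 50.0,
                      tail_ms: float = 200.0) -> ProtocolResult:
    """Evoked IPSC(s) under voltage clamp with excitation blocked.

    The Golgi-cell axon is stimulated directly (the experimental electrode
    analog): each pulse commands one presynaptic GoC spike.
    """
    if circuit.spec.n_goc < 1:
        raise ConfigurationError("IPSC protocol requires at least one GoC")
    isi = 1e3 / freq_hz
    pulses = [onset + k * isi for k in range(n_pulses)]
    duration = pulses[-1] + tail_ms
    flags = {"ampa_off": True, "nmda_off": True}
    syn = circuit.grc_synaptic_inputs([], duration, flags, goc_times=pulses)
    tr = integrate(circuit.grc, None, duration=duration, dt=circuit.dt,
                   mode=VOLTAGE_CLAMP, holding=holding, syn_inputs=syn)
    tr.meta.update(protocol="ipsc", pulses_ms=pulses)
    proto = Protocol(id="ipsc", mode=VOLTAGE_CLAMP, holding_mV=holding,
                     pulse_times_ms=pulses, flags=flags, duration_ms=duration,
                     dt_ms=circuit.dt)
    return ProtocolResult(proto, circuit.condition.name, [tr],
                          extras={"pulses_ms": pulses,
                                  "event_times_ms": [p + 1.0 for p in pulses]})


def run_epsp_protocol(circuit: Circuit, inhibition_active: bool = True,
                      holding: float = -60.0, onset_after_settle: float = 60.0,
                      settle_ms: float = 450.0, tail_ms: float = 120.0
                      ) -> ProtocolResult:
    """Subthreshold EPSP evoked by a single mossy-fiber volley, from a bias-
    held membrane potential near −60 mV.

    ``inhibition_active=False`` removes the GoCs from the circuit (null-
    inhibition configuration) rather than blocking receptors.
    """
    flags = {} if inhibition_active else {"gaba_off": True}
    stim = settle_ms + onset_after_settle
    duration = stim + tail_ms
    bias = circuit.holding_bias(holding)
    syn = circuit.grc_synaptic_inputs([stim], duration, flags)
    tr = integrate(circuit.grc, Stimulus.step(0.0, 0, 1, bias_pA=bias),
                   duration=duration, dt=circuit.dt, syn_inputs=syn)
    tr.meta.update(protocol="epsp", stim_ms=stim, bias_pA=bias)
    proto = Protocol(id="epsp", mode=CURRENT_CLAMP, holding_mV=holding,
                     pulse_times_ms=[stim], flags=flags, duration_ms=duration,
                     dt_ms=circuit.dt)
    # spikes during the settle window are accommodation transients; the
    # measurement window starts at the stimulus
    return ProtocolResult(proto, circuit.condition.name, [tr],
                          extras={"stim_ms": stim, "measure_from_ms": settle_ms})


def run_pp_frequency_sweep(circuit: Circuit, freqs_hz=(10, 20, 50, 100, 200),
                           holding: float = -60.0, settle_ms: float = 600.0,
                           window_ms: float = 100.0,
                           mf_scale: float = 3.2) -> ProtocolResult:
    """Paired mossy-fiber pulses at each input frequency; records the GrC
    voltage response for spike-count / first-spike-delay / I/O analysis.

    The default ``mf_scale`` models the suprathreshold stimulation intensity
    of the spiking protocols (the electrode is raised until the excitatory
    volley can drive the cell to threshold).
    """
    bias = circuit.holding_bias(holding)
    traces = []
    for f in freqs_hz:
        isi = 1e3 / f
        t0 = settle_ms + 50.0
        pulses = [t0, t0 + isi]
        duration = t0 + max(window_ms, isi + 50.0) + 50.0
        syn = circuit.grc_synaptic_inputs(pulses, duration, mf_scale=mf_scale)
        tr = integrate(circuit.grc, Stimulus.step(0.0, 0, 1, bias_pA=bias),
                       duration=duration, dt=circuit.dt, syn_inputs=syn)
        tr.meta.update(protocol="pp_sweep", freq_hz=float(f), pulses_ms=pulses,
                       window_ms=window_ms)
        traces.append(tr)
    proto = Protocol(id="pp_sweep", mode=CURRENT_CLAMP, holding_mV=holding,
                     duration_ms=0.0, dt_ms=circuit.dt)
    return ProtocolResult(proto, circuit.condition.name, traces,
                          extras={"freqs_hz": list(freqs_hz),
                                  "window_ms": window_ms})


def sweep_summary(result: ProtocolResult) -> dict:
    """Per-frequency spike counts, output frequency and first-spike delay."""
    out = {"freq_hz": [], "n_spikes": [], "out_hz": [], "first_delay_ms": []}
    for tr in result.traces:
        t0 = tr.meta["pulses_ms"][0]
        window = tr.meta["window_ms"]
        spikes = detect_spikes(tr)
        spikes = spikes[(spikes >= t0) & (spikes < t0 + window)]
        out["freq_hz"].append(tr.meta["freq_hz"])
        out["n_spikes"].append(int(spikes.size))
        out["out_hz"].append(1e3 * spikes.size / window)
        out["first_delay_ms"].append(float(spikes[0] - t0) if spikes.size
                                     else float("nan"))
    return {k: np.asarray(v) for k, v in out.items()}
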