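"""Synapse assembly: presynaptic dynamics + transmitter + receptor schemes.

``build_synapse`` resolves a synapse class (mf→GrC, mf→GoC, PF→GoC, AA→GoC,
GoC→GrC) against a condition bundle and returns a :class:`SynapseSpec`.
``synapse_conductances`` turns presynaptic spike times into per-receptor
conductance waveforms ready to be injected into the compartmental integrator
(or evaluated directly under ideal voltage clamp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import (ConditionSet, ConfigurationError, apply_overrides,
                         get_condition, load_synapse_params)
from .presyn import PresynapticParams, release_sequence
from .receptors import ReceptorScheme, build_scheme, mg_block, receptor_current
from .transmitter import TransmitterTimecourse, build_timecourse

SYNAPSE_CLASSES = ("mf_grc", "mf_goc", "pf_goc", "aa_goc", "goc_grc")


@dataclass
class ReceptorSlot:
    """One receptor population of a synapse with its transmitter mixing."""

    name: str
    scheme: ReceptorScheme
    input_direct: float
    input_spill: float


@dataclass
class SynapseSpec:
    """A fully resolved synapse class under a condition bundle."""

    kind: str
    condition: str
    transmitter: str
    target: str                      # postsynaptic compartment role
    presyn: PresynapticParams
    timecourse_params: dict
    receptors: list[ReceptorSlot]
    temperature_C: float

    def receptor(self, name: str) -> ReceptorSlot:
        for r in self.receptors:
            if r.name == name:
                return r
        raise KeyError(name)


def build_synapse(kind: str, condition: str | ConditionSet = "control",
                  temperature: float = 30.0) -> SynapseSpec:
    """Resolve a synapse class against a condition bundle.

    Raises ``ConfigurationError`` for unknown synapse kinds or conditions.
    """
    if kind not in SYNAPSE_CLASSES:
        raise ConfigurationError(
            f"unknown synapse class {kind!r}; known: {', '.join(SYNAPSE_CLASSES)}")
    cond = get_condition(condition) if isinstance(condition, str) else condition
    tree = load_synapse_params()
    baseline = tree["synapses"][kind]
    resolved = apply_overrides(baseline, cond.synapse_overrides(kind),
                               context=f"condition {cond.name!r} / synapse {kind!r}")
    pre = resolved["presyn"]
    presyn = PresynapticParams(
        p=pre["p"], tau_rec=pre["tau_rec_ms"], tau_facil=pre["tau_facil_ms"],
        tau_i=pre["tau_i_ms"], delay=tree.get("transmission_delay_ms", 1.0),
    )
    receptors = []
    for rname, rraw in resolved["receptors"].items():
        scheme_raw = tree["receptor_schemes"][rraw["scheme"]]
        mg = rraw.get("mg_mM")
        receptors.append(ReceptorSlot(
            name=rname,
            scheme=build_scheme(
                scheme_raw, weight_nS=rraw["weight_nS"], erev_mV=rraw["erev_mV"],
                family=rname, mg_mM=mg,
                closing_rate_scale=rraw.get("closing_rate_scale", 1.0),
                desens_recovery_scale=rraw.get("desens_recovery_scale", 1.0),
                temperature_C=temperature,
            ),
            input_direct=rraw["input"]["direct"],
            input_spill=rraw["input"]["spillover"],
        ))
    return SynapseSpec(
        kind=kind, condition=cond.name, transmitter=resolved["transmitter"],
        target=resolved["target"], presyn=presyn,
        timecourse_params=dict(resolved["timecourse"]), receptors=receptors,
        temperature_C=temperature,
    )


@dataclass
class SynapticConductance:
    """Per-receptor conductance waveform produced by a presynaptic train."""

    receptor: str
    g_nS: np.ndarray               # weight * open fraction, per sample
    erev_mV: float
    mg_mM: float | None

    def block(self):
        """Voltage-dependent conductance multiplier (NMDA Mg block), or None."""
        if self.mg_mM is None:
            return None
        mg = self.mg_mM
        return lambda v: float(mg_block(v, mg))


def synapse_conductances(spec: SynapseSpec, spike_times, duration: float,
                         dt: float, receptor_filter=None
                         ) -> tuple[list[SynapticConductance], TransmitterTimecourse, np.ndarray]:
    """Conductance waveforms for a presynaptic spike train.

    Applies the transmission delay, runs the vesicle-cycling recursion, builds
    the transmitter time course and integrates each receptor scheme.

    Parameters
    ----------
    receptor_filter : callable or None
        Optional predicate on receptor name (pharmacological flags: e.g.
        ``lambda n: n != "nmda"`` for an NMDA-blocked protocol).

    Returns
    -------
    (conductances, transmitter, released_fractions)
    """
    spike_times = np.asarray(spike_times, dtype=float)
    released = release_sequence(spike_times, spec.presyn)
    event_times = spike_times + spec.presyn.delay
    # transmitter scales with released fraction relative to the fixed
    # reference release of the synapse class (the baseline p), so condition
    # bundles that change p change the transmitter output proportionally
    rel_ref = spec.timecourse_params.get("rel_ref", 1.0)
    norm = released / rel_ref
    tc = build_timecourse(event_times, norm, spec.timecourse_params,
                          duration, dt, spec.temperature_C)
    out = []
    for slot in spec.receptors:
        if receptor_filter is not None and not receptor_filter(slot.name):
            continue
        if slot.scheme.weight_nS == 0.0:
            continue
        conc = tc.mixed(slot.input_direct, slot.input_spill)
        open_frac = slot.scheme.open_fraction(conc, dt)
        out.append(SynapticConductance(
            receptor=slot.name,
            g_nS=slot.scheme.weight_nS * open_frac,
            erev_mV=slot.scheme.erev_mV,
            mg_mM=slot.scheme.mg_mM,
        ))
    return out, tc, released


def clamp_current(conductances: list[SynapticConductance], holding_mV: float
                  ) -> np.ndarray:
    """Total synaptic clamp current (pA, outward positive) at a holding
    potential under ideal voltage clamp."""
    if not conductances:
        raise ValueError("no conductances")
    total = np.zeros_like(conductances[0].g_nS)
    for c in conductances:
        g = c.g_nS
        if c.mg_mM is not None:
            g = g * float(mg_block(holding_mV, c.mg_mM))
        total = total + g * (holding_mV - c.erev_mV)
    return total
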