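"""Cell model assembly: compartments, channels, temperature, conditions.

``build_grc`` / ``build_goc`` load the baseline parameter files, apply a
condition bundle's intrinsic overrides, apply Q10 temperature corrections and
adjust the ohmic-leak reversal so the assembled cell rests at its target
potential.  The result is a :class:`CellModel` the integrator can compile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelSpec, NapKinetics, nap_gate
from .conditions import (ConditionSet, ConfigurationError, apply_overrides,
                         get_condition, load_cell_params)
from .gating import GateSpec
from .temperature import Q10_CLASSES, TemperatureCorrection, q10_factor

FARADAY = 96485.332  # C/mol


@dataclass
class CompartmentSpec:
    """Geometry of one cylindrical compartment."""

    name: str
    role: str
    parent: int  # index of parent compartment, -1 for the root
    length_um: float
    diameter_um: float

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError(f"compartment {self.name!r}: geometry must be positive")

    @property
    def area_um2(self) -> float:
        return math.pi * self.diameter_um * self.length_um


@dataclass
class CompiledChannel:
    """A channel instance bound to a compartment with absolute conductance."""

    name: str
    comp: int
    gbar_nS: float
    erev_mV: float
    gates: list[GateSpec] = field(default_factory=list)
    rate_factor: float = 1.0
    ca_gate: dict | None = None
    is_ca_source: bool = False


@dataclass
class CellModel:
    """An assembled, temperature-corrected, condition-resolved cell."""

    kind: str
    compartments: list[CompartmentSpec]
    cap_pF: np.ndarray            # per compartment
    g_axial_nS: np.ndarray        # coupling conductance to parent, per compartment
    channels: list[CompiledChannel]
    ca_pool: dict | None
    temperature_C: float
    condition: str
    rest_target_mV: float
    params: dict                  # resolved parameter tree (after overrides)

    @property
    def n_comp(self) -> int:
        return len(self.compartments)

    def comp_index(self, name: str) -> int:
        for i, c in enumerate(self.compartments):
            if c.name == name:
                return i
        raise KeyError(name)

    def channel(self, name: str, comp: str | None = None) -> CompiledChannel:
        for ch in self.channels:
            if ch.name == name and (comp is None or
                                    self.compartments[ch.comp].name == comp):
                return ch
        raise KeyError((name, comp))

    def steady_state_currents(self, v_mV: float) -> np.ndarray:
        """Per-compartment ionic current (pA, outward positive) at uniform
        voltage with all gates at steady state and Ca at rest."""
        out = np.zeros(self.n_comp)
        varr = np.array([v_mV])
        ca_rest = self.ca_pool["ca_rest_mM"] if self.ca_pool else 1e-4
        for ch in self.channels:
            gfrac = 1.0
            for g in ch.gates:
                xinf, _ = g.curves(varr, rate_factor=ch.rate_factor)
                gfrac *= float(xinf[0]) ** g.exponent
            if ch.ca_gate is not None:
                kd = ch.ca_gate["kd_mM"]
                gfrac *= (ca_rest / (ca_rest + kd)) ** ch.ca_gate.get("exponent", 1)
            out[ch.comp] += ch.gbar_nS * gfrac * (v_mV - ch.erev_mV)
        return out

    def holding_current_pA(self, v_mV: float) -> float:
        """Injected current required to hold the whole cell at ``v_mV`` at
        steady state (positive = depolarizing... sign: outward ionic current
        must be supplied by the electrode)."""
        return float(np.sum(self.steady_state_currents(v_mV)))


def _axial_r_Mohm(comp: CompartmentSpec, ra_ohm_cm: float) -> float:
    """Half axial resistance of a compartment in MOhm."""
    # Ra [ohm cm] * (L/2 [cm]) / (area [cm^2]); lengths um -> cm: *1e-4
    length_cm = comp.length_um * 1e-4 / 2.0
    radius_cm = comp.diameter_um * 1e-4 / 2.0
    r_ohm = ra_ohm_cm * length_cm / (math.pi * radius_cm ** 2)
    return r_ohm / 1e6


def _build_gates(chan_raw: dict) -> list[GateSpec]:
    gates = []
    for graw in chan_raw.get("gates", []):
        gates.append(GateSpec(
            name=graw["name"],
            form=graw["form"],
            params=dict(graw["params"]),
            exponent=int(graw.get("exponent", 1)),
            q10_class=graw.get("q10_class", "gating"),
        ))
    return gates


def build_cell(kind: str, condition: str | ConditionSet = "control",
               temperature: float = 30.0) -> CellModel:
    """Assemble a cell model for a condition bundle at a simulation temperature."""
    if not (20.0 <= temperature <= 40.0):
        raise ConfigurationError(
            f"simulation temperature {temperature} degC outside supported [20, 40]")
    cond = get_condition(condition) if isinstance(condition, str) else condition
    params = apply_overrides(load_cell_params(kind), cond.cell_overrides(kind),
                             context=f"condition {cond.name!r} / cell {kind!r}")

    ra = params["axial_resistivity_ohm_cm"]
    cap_density = params["capacitance_uF_per_cm2"]

    comps: list[CompartmentSpec] = []
    name_to_idx: dict[str, int] = {}
    for raw in params["compartments"]:
        parent = -1 if raw["parent"] in (None, "null") else name_to_idx[raw["parent"]]
        comp = CompartmentSpec(raw["name"], raw["role"], parent,
                               raw["length_um"], raw["diameter_um"])
        name_to_idx[comp.name] = len(comps)
        comps.append(comp)

    cap = np.array([c.area_um2 * cap_density / 100.0 for c in comps])  # pF
    g_axial = np.zeros(len(comps))
    for i, c in enumerate(comps):
        if c.parent >= 0:
            r = _axial_r_Mohm(c, ra) + _axial_r_Mohm(comps[c.parent], ra)
            g_axial[i] = 1e3 / r  # 1/MOhm = uS -> nS: *1e3

    tc = TemperatureCorrection(temperature)
    channels: list[CompiledChannel] = []
    for cname, raw in params["channels"].items():
        t_orig = raw.get("t_orig_C", 37.0)
        perm = tc.factor("permeation", t_orig)
        gate_rate = tc.factor("gating", t_orig)
        if "kinetics" in raw:  # persistent Na: time-scale parameterization
            kin = NapKinetics(raw["kinetics"]["a_on"], raw["kinetics"]["a_off"])
            gates = [nap_gate(kin, raw["gate_shape"])] + _build_gates(raw)
        else:
            gates = _build_gates(raw)
        for g in gates:
            g.validate()
        for comp_name, density in raw["density_S_per_cm2"].items():
            if comp_name not in name_to_idx:
                raise ConfigurationError(
                    f"channel {cname!r} placed on unknown compartment {comp_name!r}")
            idx = name_to_idx[comp_name]
            gbar = density * comps[idx].area_um2 * 10.0 * perm  # nS
            channels.append(CompiledChannel(
                name=cname, comp=idx, gbar_nS=gbar, erev_mV=raw["erev_mV"],
                gates=gates, rate_factor=gate_rate,
                ca_gate=raw.get("ca_gate"), is_ca_source=raw.get("ca_source", False),
            ))

    ca_pool = None
    if "ca_pool" in params:
        cp = dict(params["ca_pool"])
        cp["tau_ms"] = cp["tau_ms"] / tc.factor("ca_pump", cp.get("t_orig_C", 37.0))
        ca_pool = cp

    model = CellModel(
        kind=kind, compartments=comps, cap_pF=cap, g_axial_nS=g_axial,
        channels=channels, ca_pool=ca_pool, temperature_C=temperature,
        condition=cond.name, rest_target_mV=params["resting_potential_mV"],
        params=params,
    )
    _adjust_leak_reversal(model)
    return model


def _adjust_leak_reversal(model: CellModel) -> None:
    """Shift the ohmic-leak reversal so every compartment carries zero net
    ionic current at the resting target (the in-vivo adaptation step of the
    base model: "leakage reversal adjusted to restore resting potential")."""
    v = model.rest_target_mV
    adjustable = [ch for ch in model.channels
                  if model.params["channels"][ch.name].get("adjust_erev_for_rest")]
    if not adjustable:
        return
    currents = model.steady_state_currents(v)
    for comp in range(model.n_comp):
        leaks = [ch for ch in adjustable if ch.comp == comp]
        if not leaks:
            continue
        g_leak = sum(ch.gbar_nS for ch in leaks)
        other = currents[comp] - sum(ch.gbar_nS * (v - ch.erev_mV) for ch in leaks)
        erev = v + other / g_leak
        for ch in leaks:
            ch.erev_mV = erev


def build_grc(condition: str | ConditionSet = "control",
              temperature: float = 30.0) -> CellModel:
    """Granule-cell model for a condition bundle (see ``build_cell``)."""
    return build_cell("grc", condition, temperature)


def build_goc(condition: str | ConditionSet = "control",
              temperature: float = 30.0) -> CellModel:
    """Golgi-cell model (reduced spiking compartment) for a condition bundle."""
    return build_cell("goc", condition, temperature)
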