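"""Fixed-step integrator for compartmental cell models.

The scheme follows standard compartmental-simulator practice: gating
variables advance by exact exponential relaxation toward their
voltage-dependent steady state (rates tabulated on a voltage grid and
linearly interpolated), and the voltage step solves the coupled compartment
system implicitly with a theta-rule (theta = 0.5, Crank–Nicolson-like),
staggered against the gate update.  dt-halving convergence is part of the
test suite.

Current clamp records the somatic membrane potential; voltage clamp holds
every compartment at the command potential (ideal whole-cell clamp of an
electrotonically compact cell) and records the total clamp current.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .cell import CellModel, FARADAY
from .gating import V_GRID_MIN, V_GRID_STEP, voltage_grid
from .trace import CURRENT, VOLTAGE, Trace

CURRENT_CLAMP = "current-clamp"
VOLTAGE_CLAMP = "voltage-clamp"


class IntegrationError(RuntimeError):
    """Raised when the solution becomes non-finite; names the failing time."""


@dataclass
class Stimulus:
    """Injected-current waveform (pA) for current-clamp protocols."""

    segments: list = field(default_factory=list)  # (t0, t1, amplitude)
    bias_pA: float = 0.0

    @classmethod
    def zero(cls) -> "Stimulus":
        return cls()

    @classmethod
    def step(cls, amplitude_pA: float, t_start: float, t_stop: float,
             bias_pA: float = 0.0) -> "Stimulus":
        return cls(segments=[(t_start, t_stop, amplitude_pA)], bias_pA=bias_pA)

    @classmethod
    def pulses(cls, times_ms, amplitude_pA: float, width_ms: float,
               bias_pA: float = 0.0) -> "Stimulus":
        return cls(segments=[(t, t + width_ms, amplitude_pA) for t in times_ms],
                   bias_pA=bias_pA)

    @classmethod
    def ramped_hold(cls, bias_pA: float, ramp_ms: float,
                    extra: "Stimulus | None" = None) -> "Stimulus":
        """Bias reached along a linear ramp (gentle approach to a holding
        point), optionally combined with another stimulus."""
        stim = cls(segments=list(extra.segments) if extra else [],
                   bias_pA=bias_pA)
        stim.ramp_ms = ramp_ms
        return stim

    ramp_ms: float = 0.0

    def current(self, t: np.ndarray) -> np.ndarray:
        i = np.full(t.shape, self.bias_pA, dtype=np.float64)
        if self.ramp_ms > 0:
            i *= np.clip(t / self.ramp_ms, 0.0, 1.0)
        for t0, t1, amp in self.segments:
            i[(t >= t0) & (t < t1)] += amp
        return i


@dataclass
class SynapticInput:
    """Precomputed synaptic conductance waveform applied to one compartment.

    ``block`` is an optional voltage-dependent multiplier on the conductance
    (the NMDA Mg block), evaluated at the instantaneous membrane potential.
    """

    comp: int
    g_nS: np.ndarray
    erev_mV: float
    block: Callable[[float], float] | None = None


class _Compiled:
    """Flat-array view of a CellModel for the inner loop."""

    def __init__(self, cell: CellModel):
        self.cell = cell
        vgrid = voltage_grid()
        tables_inf: list[np.ndarray] = []
        tables_tau: list[np.ndarray] = []
        table_key: dict = {}

        g_table, g_comp, g_exp, g_chan = [], [], [], []
        ca_gates = []  # (chan_idx, kd, exponent, tau_ms)
        n_chan = len(cell.channels)
        self.chan_gbar = np.array([ch.gbar_nS for ch in cell.channels])
        self.chan_erev = np.array([ch.erev_mV for ch in cell.channels])
        self.chan_comp = np.array([ch.comp for ch in cell.channels], dtype=np.intp)
        self.ca_source = np.array([ch.is_ca_source for ch in cell.channels])

        for ci, ch in enumerate(cell.channels):
            for gate in ch.gates:
                key = (id(gate), ch.rate_factor)
                if key not in table_key:
                    xinf, tau = gate.curves(vgrid, rate_factor=ch.rate_factor)
                    table_key[key] = len(tables_inf)
                    tables_inf.append(xinf)
                    tables_tau.append(tau)
                g_table.append(table_key[key])
                g_comp.append(ch.comp)
                g_exp.append(gate.exponent)
                g_chan.append(ci)
            if ch.ca_gate is not None:
                ca_gates.append((ci, ch.ca_gate["kd_mM"],
                                 ch.ca_gate.get("exponent", 1),
                                 ch.ca_gate["tau_ms"] / ch.rate_factor))

        self.tab_inf = np.array(tables_inf) if tables_inf else np.zeros((0, vgrid.size))
        self.tab_tau = np.array(tables_tau) if tables_tau else np.zeros((0, vgrid.size))
        self.g_table = np.array(g_table, dtype=np.intp)
        self.g_comp = np.array(g_comp, dtype=np.intp)
        self.g_exp = np.array(g_exp, dtype=np.float64)
        self.g_chan = np.array(g_chan, dtype=np.intp)
        self.n_chan = n_chan
        self.ca_gates = ca_gates

        n = cell.n_comp
        lap = np.zeros((n, n))
        for i, c in enumerate(cell.compartments):
            if c.parent >= 0:
                g = cell.g_axial_nS[i]
                lap[i, i] += g
                lap[c.parent, c.parent] += g
                lap[i, c.parent] -= g
                lap[c.parent, i] -= g
        self.laplacian = lap

        # Ca pool geometry per compartment hosting a Ca source
        self.ca_coef = np.zeros(n)
        if cell.ca_pool is not None:
            depth = cell.ca_pool["shell_depth_um"]
            for i, c in enumerate(cell.compartments):
                vol_L = c.area_um2 * depth * 1e-15
                self.ca_coef[i] = 1e-12 / (2.0 * FARADAY * vol_L)

    def gate_lookup(self, x_v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pos = (x_v - V_GRID_MIN) / V_GRID_STEP
        np.clip(pos, 0.0, self.tab_inf.shape[1] - 1.001, out=pos)
        i0 = pos.astype(np.intp)
        frac = pos - i0
        inf = self.tab_inf[self.g_table, i0] * (1 - frac) + \
            self.tab_inf[self.g_table, i0 + 1] * frac
        tau = self.tab_tau[self.g_table, i0] * (1 - frac) + \
            self.tab_tau[self.g_table, i0 + 1] * frac
        return inf, tau


def _init_state(comp: _Compiled, v0: float):
    x_inf, _ = comp.gate_lookup(np.full(comp.g_comp.shape, v0))
    ca0 = comp.cell.ca_pool["ca_rest_mM"] if comp.cell.ca_pool else 1e-4
    ca = np.full(comp.cell.n_comp, ca0)
    ca_gate_x = {ci: ca0 / (ca0 + kd) for ci, kd, _e, _t in comp.ca_gates}
    return x_inf.copy(), ca, ca_gate_x


def integrate(cell: CellModel, stimulus: Stimulus | None = None,
              duration: float = 500.0, dt: float = 0.025,
              mode: str = CURRENT_CLAMP, holding: float | None = None,
              syn_inputs: tuple[SynapticInput, ...] | list = (),
              v_init: float | None = None, record: str = "soma",
              theta: float = 0.5, debug_checks: bool = False) -> Trace:
    """Integrate a cell model under a stimulation protocol.

    Parameters
    ----------
    cell : CellModel
        Assembled cell (see :func:`grcmicro.cell.build_cell`).
    stimulus : Stimulus, optional
        Injected current (current clamp only).
    duration, dt : float
        Simulated time and fixed step, ms.  ``dt`` must be <= 0.05 ms.
    mode : str
        ``"current-clamp"`` (records soma voltage, mV) or ``"voltage-clamp"``
        (records total clamp current, pA; ``holding`` required).
    syn_inputs : sequence of SynapticInput
        Precomputed synaptic conductance waveforms, sampled at the same dt on
        ``duration`` (length >= n_steps + 1).
    v_init : float, optional
        Initial uniform potential; defaults to the cell's resting target (or
        the holding potential in voltage clamp).

    Returns
    -------
    Trace
        Somatic voltage or clamp current, sampled at dt.
    """
    if dt > 0.05 + 1e-12:
        raise ValueError(f"dt must be <= 0.05 ms, got {dt}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == VOLTAGE_CLAMP and holding is None:
        raise ValueError("voltage clamp requires a holding potential")

    comp = _Compiled(cell)
    n = cell.n_comp
    n_steps = int(round(duration / dt))
    t = dt * np.arange(n_steps + 1)

    if v_init is None:
        v_init = holding if mode == VOLTAGE_CLAMP else cell.rest_target_mV
    v = np.full(n, float(v_init))
    x, ca, ca_gate_x = _init_state(comp, float(v_init))

    i_ext = np.zeros((n_steps + 1,))
    if stimulus is not None:
        if mode == VOLTAGE_CLAMP:
            raise ValueError("current stimulus is a current-clamp concept")
        i_ext = stimulus.current(t)
    soma = cell.comp_index(record) if isinstance(record, str) else record

    for s in syn_inputs:
        if len(s.g_nS) < n_steps + 1:
            raise ValueError("synaptic conductance waveform shorter than protocol")

    out = np.empty(n_steps + 1)
    cap_dt = cell.cap_pF / dt
    lap = comp.laplacian
    eye = np.eye(n)
    ca_pool = cell.ca_pool
    vclamp = mode == VOLTAGE_CLAMP

    g_chan = np.empty(comp.n_chan)
    for step in range(n_steps + 1):
        # --- gate update (exponential relaxation toward tabulated steady state)
        vg = v[comp.g_comp]
        xinf, tau = comp.gate_lookup(vg)
        if step > 0:
            x = xinf + (x - xinf) * np.exp(-dt / tau)
            if debug_checks and (np.any(x < -1e-9) or np.any(x > 1 + 1e-9)):
                raise IntegrationError(f"gating variable left [0,1] at t={step * dt:.3f} ms")

        # --- channel conductances
        g_chan[:] = comp.chan_gbar
        np.multiply.at(g_chan, comp.g_chan, x ** comp.g_exp)
        for ci, kd, expn, tau_ms in comp.ca_gates:
            cinf = (ca[comp.chan_comp[ci]] / (ca[comp.chan_comp[ci]] + kd)) ** expn
            if step > 0:
                ca_gate_x[ci] = cinf + (ca_gate_x[ci] - cinf) * np.exp(-dt / tau_ms)
            g_chan[ci] *= ca_gate_x[ci]

        g_tot = np.zeros(n)
        ge_tot = np.zeros(n)
        np.add.at(g_tot, comp.chan_comp, g_chan)
        np.add.at(ge_tot, comp.chan_comp, g_chan * comp.chan_erev)

        # --- synaptic conductances
        for s in syn_inputs:
            g = s.g_nS[step]
            if s.block is not None:
                g = g * s.block(v[s.comp])
            g_tot[s.comp] += g
            ge_tot[s.comp] += g * s.erev_mV

        if vclamp:
            # ideal clamp: record total membrane current at the command voltage
            out[step] = float(np.sum(g_tot * v - ge_tot))
        else:
            out[step] = v[soma]
            # --- implicit theta step for the voltage system
            rhs = cap_dt * v - (1 - theta) * (g_tot * v - ge_tot + lap @ v) \
                + theta * ge_tot
            rhs[soma] += i_ext[step]
            m = cap_dt[:, None] * eye + theta * (np.diag(g_tot) + lap)
            v = np.linalg.solve(m, rhs)

        # --- Ca pool (explicit, driven by Ca-source channel currents)
        if ca_pool is not None:
            i_ca = np.zeros(n)
            src = comp.ca_source
            if np.any(src):
                np.add.at(i_ca, comp.chan_comp[src],
                          g_chan[src] * (v[comp.chan_comp[src]] - comp.chan_erev[src]))
                dca = -comp.ca_coef * i_ca - (ca - ca_pool["ca_rest_mM"]) / ca_pool["tau_ms"]
                ca = np.maximum(ca + dt * dca, 1e-9)

        if step % 400 == 0 and not np.all(np.isfinite(v)):
            raise IntegrationError(f"non-finite state at t={step * dt:.3f} ms")

    if not np.all(np.isfinite(out)):
        bad = int(np.argmax(~np.isfinite(out)))
        raise IntegrationError(f"non-finite output at t={bad * dt:.3f} ms")

    kind = CURRENT if vclamp else VOLTAGE
    return Trace(dt=dt, data=out, kind=kind, t0=0.0, meta={
        "mode": mode, "cell": cell.kind, "condition": cell.condition,
        "temperature_C": cell.temperature_C, "holding_mV": holding,
    })
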