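"""Multi-state postsynaptic receptor kinetics.

Each receptor family (AMPA, NMDA, GABA-A alpha1/alpha6, kainate) is a
first-order kinetic scheme over closed, open and desensitized states whose
ligand-binding transitions scale with the transmitter concentration.  The
occupancy vector evolves under a conservative generator matrix (columns sum
to zero), integrated with a backward-Euler step that preserves total
occupancy to machine precision.  The NMDA current is additionally multiplied
by the voltage-dependent magnesium block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .temperature import q10_factor

#: Jahr–Stevens-type Mg-block parameters (mM, mV).
MG_BLOCK_K_MM = 3.57
MG_BLOCK_V0_MV = 16.13


def mg_block(v_mV, mg_mM: float, k_mM: float = MG_BLOCK_K_MM,
             v0_mV: float = MG_BLOCK_V0_MV):
    """Voltage-dependent Mg-block factor of the NMDA receptor, in (0, 1].

    ``B(V) = 1 / (1 + [Mg]/K · exp(−V/v0))`` — monotonically non-decreasing
    in V and exactly 1 in Mg-free conditions.
    """
    if np.any(np.asarray(mg_mM) < 0):
        raise ValueError("Mg concentration must be non-negative")
    return 1.0 / (1.0 + (mg_mM / k_mM) * np.exp(-np.asarray(v_mV, dtype=float) / v0_mV))


class SchemeDefinitionError(ValueError):
    """Raised when a kinetic scheme is not conservative or malformed."""


@dataclass
class ReceptorScheme:
    """A receptor kinetic scheme bound to one synaptic contact.

    Parameters
    ----------
    family : str
        ``ampa`` | ``nmda`` | ``gabaa_a1`` | ``gabaa_a6`` | ``kainate``.
    states : list of str
    open_states : list of str
    transitions : list of dict
        Each ``{"from", "to", "rate"}`` plus optional flags ``ligand``
        (rate multiplies the transmitter concentration), ``closing`` and
        ``recovery`` (rates subject to per-synapse scale factors).
    weight_nS : float
        Maximal open-state conductance of the contact.
    erev_mV : float
    mg_mM : float or None
        Extracellular Mg for the block factor (NMDA only; None disables).
    rate_factor : float
        Q10 temperature multiplier applied to every transition rate.
    """

    family: str
    states: list
    open_states: list
    transitions: list
    weight_nS: float
    erev_mV: float
    mg_mM: float | None = None
    rate_factor: float = 1.0

    def __post_init__(self) -> None:
        idx = {s: i for i, s in enumerate(self.states)}
        if len(idx) != len(self.states):
            raise SchemeDefinitionError("duplicate state names")
        missing = [s for s in self.open_states if s not in idx]
        if missing or not self.open_states:
            raise SchemeDefinitionError(f"bad open states: {self.open_states}")
        self._idx = idx
        n = len(self.states)
        self._q_base = np.zeros((n, n))    # concentration-independent part
        self._q_ligand = np.zeros((n, n))  # part multiplying [transmitter]
        for tr in self.transitions:
            i, j = idx[tr["from"]], idx[tr["to"]]
            rate = tr["rate"] * self.rate_factor
            target = self._q_ligand if tr.get("ligand") else self._q_base
            target[j, i] += rate
            target[i, i] -= rate
        for q in (self._q_base, self._q_ligand):
            if np.max(np.abs(q.sum(axis=0))) > 1e-12:
                raise SchemeDefinitionError("generator columns do not conserve occupancy")
        self._open_idx = np.array([idx[s] for s in self.open_states])

    @property
    def n_states(self) -> int:
        return len(self.states)

    def resting_occupancy(self) -> np.ndarray:
        x = np.zeros(self.n_states)
        x[0] = 1.0
        return x

    def open_fraction(self, concentration: np.ndarray, dt: float,
                      x0: np.ndarray | None = None,
                      conservation_tol: float = 1e-9) -> np.ndarray:
        """Open-state occupancy over time for a transmitter waveform.

        Backward-Euler integration of ``dx/dt = Q(C(t)) x``; total occupancy
        is conserved exactly by construction and asserted to
        ``conservation_tol``.
        """
        c = np.asarray(concentration, dtype=float)
        if np.any(c < 0):
            raise ValueError("transmitter concentration must be non-negative")
        n = self.n_states
        x = self.resting_occupancy() if x0 is None else np.asarray(x0, float).copy()
        eye = np.eye(n)
        out = np.empty(c.size)
        out[0] = x[self._open_idx].sum()
        for k in range(1, c.size):
            q = self._q_base + c[k] * self._q_ligand
            x = np.linalg.solve(eye - dt * q, x)
            out[k] = x[self._open_idx].sum()
        if abs(x.sum() - 1.0) > conservation_tol:
            raise SchemeDefinitionError(
                f"occupancy drifted to {x.sum()!r} (conservation violated)")
        return out


def build_scheme(raw: dict, weight_nS: float, erev_mV: float,
                 family: str, mg_mM: float | None = None,
                 closing_rate_scale: float = 1.0,
                 desens_recovery_scale: float = 1.0,
                 temperature_C: float = 30.0) -> ReceptorScheme:
    """Instantiate a scheme from its parameter-file dict, applying the
    per-synapse closing/recovery scale factors and receptor-gating Q10."""
    transitions = []
    for tr in raw["transitions"]:
        tr = dict(tr)
        if tr.get("closing"):
            tr["rate"] = tr["rate"] * closing_rate_scale
        if tr.get("recovery"):
            tr["rate"] = tr["rate"] * desens_recovery_scale
        transitions.append(tr)
    rf = q10_factor(2.4, raw.get("t_orig_C", 37.0), temperature_C)
    return ReceptorScheme(
        family=family, states=list(raw["states"]),
        open_states=list(raw["open_states"]), transitions=transitions,
        weight_nS=weight_nS, erev_mV=erev_mV, mg_mM=mg_mM, rate_factor=rf,
    )


def receptor_current(scheme: ReceptorScheme, concentration: np.ndarray,
                     v_mV, dt: float) -> np.ndarray:
    """Postsynaptic current (pA, outward positive) under a transmitter
    waveform at fixed or time-varying holding potential.

    ``I = weight · open(t) · (V − E_rev) · B(V)`` with B the Mg block for
    NMDA-family schemes.
    """
    open_frac = scheme.open_fraction(concentration, dt)
    v = np.asarray(v_mV, dtype=float)
    block = 1.0
    if scheme.mg_mM is not None:
        block = mg_block(v, scheme.mg_mM)
    return scheme.weight_nS * open_frac * (v - scheme.erev_mV) * block
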