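"""Deterministic mean-field vesicle-cycling presynaptic dynamics.

The release machinery follows the Tsodyks–Markram family with a three-state
vesicle pool — recovered (x), effective/releasable-in-cleft (y), inactive (z)
— and a facilitation variable u.  At each presynaptic spike u jumps by
``U·(1−u)`` *before* release and the released fraction is ``u·x``; between
spikes y drains into z with ``tau_i``, z recovers into x with ``tau_rec`` and
u relaxes back to zero with ``tau_facil``.  With baseline ``U = p`` the first
release of a resting train equals the release probability p exactly.

The pool fractions are advanced with the closed-form solution of the linear
inter-spike kinetics, so x + y + z = 1 holds to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PresynapticParams:
    """Vesicle-cycling parameters of one synapse class.

    p : release probability (baseline facilitation increment U), dimensionless
    tau_rec : recovery from depression, ms
    tau_facil : decay of facilitation, ms
    tau_i : vesicle inactivation (drain of the effective pool), ms
    delay : axonal+synaptic transmission delay, ms (1 ms for all synapses)
    """

    p: float
    tau_rec: float
    tau_facil: float
    tau_i: float
    delay: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"release probability must be in [0, 1], got {self.p}")
        for name in ("tau_rec", "tau_facil", "tau_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PresynapticState:
    """Pool fractions and facilitation state between updates."""

    recovered: float = 1.0
    effective: float = 0.0
    inactive: float = 0.0
    u: float = 0.0
    t_last: float = -math.inf

    def check(self, tol: float = 1e-9) -> None:
        total = self.recovered + self.effective + self.inactive
        if abs(total - 1.0) > tol:
            raise AssertionError(f"vesicle pool not conserved: sum={total!r}")
        if not -tol <= self.u <= 1.0 + tol:
            raise AssertionError(f"facilitation u outside [0,1]: {self.u!r}")

    def relax(self, dt: float, p: PresynapticParams) -> None:
        """Advance the pools by ``dt`` ms with no spike (closed form)."""
        if dt <= 0:
            return
        ti, tr = p.tau_i, p.tau_rec
        y0, z0 = self.effective, self.inactive
        ey = math.exp(-dt / ti)
        ez = math.exp(-dt / tr)
        if abs(ti - tr) < 1e-9:
            # degenerate equal-time-constant limit
            a = y0 * dt / tr
            y = y0 * ey
            z = (z0 + a) * ez
        else:
            a = y0 * tr / (ti - tr)
            y = y0 * ey
            z = (z0 - a) * ez + a * ey
        self.effective = y
        self.inactive = z
        self.recovered = 1.0 - y - z
        self.u *= math.exp(-dt / p.tau_facil)

    def spike(self, p: PresynapticParams) -> float:
        """Apply a spike: facilitation jump, then release.  Returns the
        released pool fraction."""
        self.u += p.p * (1.0 - self.u)
        delta = self.u * self.recovered
        self.recovered -= delta
        self.effective += delta
        return delta


def release_sequence(spike_times, params: PresynapticParams,
                     check_conservation: bool = True) -> np.ndarray:
    """Released pool fraction for each spike of a presynaptic train.

    Parameters
    ----------
    spike_times : array-like
        Strictly increasing spike times, ms.
    params : PresynapticParams

    Returns
    -------
    ndarray
        One released fraction in [0, 1] per spike; the first release of a
        resting train equals ``params.p``.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.ndim != 1:
        raise ValueError("spike times must be one-dimensional")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("spike times must be strictly increasing")
    state = PresynapticState()
    out = np.empty(t.size)
    prev = None
    for i, ti in enumerate(t):
        if prev is not None:
            state.relax(ti - prev, params)
        out[i] = state.spike(params)
        if check_conservation:
            state.check()
        prev = ti
    return out
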