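"""Hodgkin–Huxley-style gating kinetics.

Two parameterizations are supported, mirroring how conductance-based cell
models are published:

``inf_tau``
    Boltzmann steady state ``x_inf(V) = 1/(1+exp(-(V-vhalf)/k))`` (``k`` may be
    negative for inactivation/inward-rectifying gates) plus a bell-shaped
    voltage-dependent time constant.

``rates``
    Bounded forward/backward rate functions
    ``alpha(V) = a_scale / (1+exp(-(V-va)/ka))`` and
    ``beta(V) = b_scale / (1+exp((V-vb)/kb))`` with
    ``x_inf = alpha/(alpha+beta)`` and ``tau = 1/(alpha+beta)``.  The
    persistent-Na gate uses this form: its ``a_scale``/``b_scale`` are the
    activation/deactivation kinetic scale parameters (the quantities the
    anesthetic condition rescales).

Both forms guarantee finite rates and ``x_inf`` in [0, 1] on the physiological
voltage range.  For simulation the curves are tabulated on a fixed voltage
grid and linearly interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Voltage grid used for rate tables (mV).
V_GRID_MIN = -120.0
V_GRID_MAX = 80.0
V_GRID_STEP = 0.05


def voltage_grid() -> np.ndarray:
    n = int(round((V_GRID_MAX - V_GRID_MIN) / V_GRID_STEP)) + 1
    return V_GRID_MIN + V_GRID_STEP * np.arange(n)


@dataclass
class GateSpec:
    """One gating variable of a channel.

    Parameters
    ----------
    name : str
        Variable name (``m``, ``h``, ``n`` ...).
    form : str
        ``"inf_tau"`` or ``"rates"``.
    params : dict
        Parameters of the chosen form (see module docstring).
    exponent : int
        Power to which the variable is raised in the conductance product.
    q10_class : str
        Process class used for temperature correction of the kinetics.
    """

    name: str
    form: str
    params: dict
    exponent: int = 1
    q10_class: str = "gating"

    def curves(self, v: np.ndarray, rate_factor: float = 1.0,
               tau_min: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
        """Steady state and time constant over voltages ``v``.

        ``rate_factor`` is the Q10 multiplier applied to the underlying rates
        (time constants divide by it).
        """
        p = self.params
        if self.form == "inf_tau":
            xinf = 1.0 / (1.0 + np.exp(-(v - p["vhalf"]) / p["k"]))
            sigma2 = p.get("sigma2", p["sigma"])
            tau = p.get("tau_min", 0.0) + p["tau_amp"] / (
                np.exp((v - p["vtau"]) / p["sigma"])
                + np.exp(-(v - p["vtau"]) / sigma2)
            )
            tau = tau / rate_factor
        elif self.form == "rates_exp":
            # exponential forward/backward rates: Boltzmann steady state with
            # midpoint set by the rate-scale ratio; bell-shaped time constant
            alpha = rate_factor * p["a_scale"] * np.exp((v - p["v0"]) / p["ka"])
            beta = rate_factor * p["b_scale"] * np.exp(-(v - p["v0"]) / p["kb"])
            tot = alpha + beta
            xinf = alpha / tot
            tau = 1.0 / tot
        elif self.form == "rates":
            alpha = rate_factor * p["a_scale"] / (1.0 + np.exp(-(v - p["va"]) / p["ka"]))
            beta = rate_factor * p["b_scale"] / (1.0 + np.exp((v - p["vb"]) / p["kb"]))
            tot = alpha + beta
            xinf = alpha / tot
            tau = 1.0 / tot
        else:
            raise ValueError(f"unknown gating form {self.form!r}")
        tau = np.maximum(tau, tau_min)
        if not (np.all(np.isfinite(xinf)) and np.all(np.isfinite(tau))):
            raise ValueError(f"gate {self.name!r}: non-finite kinetics")
        return xinf, tau

    def validate(self) -> None:
        """Check invariants on the physiological voltage range [-100, 60] mV."""
        v = np.linspace(-100.0, 60.0, 321)
        xinf, tau = self.curves(v)
        if np.any(xinf < -1e-12) or np.any(xinf > 1 + 1e-12):
            raise ValueError(f"gate {self.name!r}: steady state outside [0, 1]")
        if np.any(tau <= 0):
            raise ValueError(f"gate {self.name!r}: non-positive time constant")


@dataclass
class GatingScheme:
    """Ordered set of gating variables of one channel."""

    gates: list[GateSpec] = field(default_factory=list)

    def validate(self) -> None:
        for g in self.gates:
            g.validate()
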