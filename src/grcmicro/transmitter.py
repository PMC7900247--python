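"""Transmitter concentration time courses with glomerular spillover.

Each release event produces a direct synaptic-cleft component (a square
pulse, ~1 ms) and a slower glomerular spillover component (instant rise,
exponential decay).  Both scale linearly with the released vesicle-pool
fraction of the event.  The spillover decay carries the transmitter-diffusion
Q10 class, so cooling from the reference temperature slows the glomerular
component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .temperature import q10_factor


@dataclass
class TransmitterTimecourse:
    """Direct and spillover concentration waveforms (mM) on a fixed grid."""

    dt: float
    direct: np.ndarray
    spillover: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.direct < 0) or np.any(self.spillover < 0):
            raise ValueError("transmitter concentration must be non-negative")

    def mixed(self, w_direct: float, w_spill: float) -> np.ndarray:
        """Effective concentration seen by a receptor population."""
        return w_direct * self.direct + w_spill * self.spillover


def build_timecourse(event_times, released_fractions, params: dict,
                     duration: float, dt: float,
                     temperature_C: float = 30.0) -> TransmitterTimecourse:
    """Transmitter waveforms for a sequence of release events.

    Parameters
    ----------
    event_times : array-like, ms
        Times transmitter enters the cleft (presynaptic spike + delay).
    released_fractions : array-like
        Released pool fraction per event (scales both components linearly;
        normalized so a fraction equal to the resting release probability
        yields the nominal peak concentrations).
    params : dict
        ``direct_peak_mM``, ``direct_width_ms``, ``spill_peak_mM``,
        ``spill_tau_ms``, ``t_orig_C`` (from the synapse parameter file).
    """
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    direct = np.zeros(n)
    spill = np.zeros(n)
    diff_rf = q10_factor(1.3, params.get("t_orig_C", 37.0), temperature_C)
    spill_tau = params["spill_tau_ms"] / diff_rf
    width = params["direct_width_ms"]
    for t0, rel in zip(np.asarray(event_times, float),
                       np.asarray(released_fractions, float)):
        if rel < 0:
            raise ValueError("released fraction must be non-negative")
        in_pulse = (t >= t0) & (t < t0 + width)
        direct[in_pulse] += params["direct_peak_mM"] * rel
        after = t >= t0
        spill[after] += params["spill_peak_mM"] * rel * np.exp(-(t[after] - t0) / spill_tau)
    return TransmitterTimecourse(dt=dt, direct=direct, spillover=spill)
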