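"""Uniformly sampled time series produced by simulation, synthesis, or recording.

Unit system used throughout the package: mV, ms, pA, nS, pF, mM, µm.
Conversions from parameter-file units (S/cm², µF/cm²) happen only when a cell
model is compiled for simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VOLTAGE = "voltage"
CURRENT = "current"
_KINDS = (VOLTAGE, CURRENT)


@dataclass
class Trace:
    """A uniformly sampled voltage (mV) or current (pA) time series.

    Parameters
    ----------
    dt : float
        Sampling interval in ms; must be positive.
    data : ndarray
        Sample values (mV for voltage, pA for current).
    kind : str
        ``"voltage"`` or ``"current"``.
    t0 : float
        Time of the first sample, ms.
    meta : dict
        Free-form provenance (protocol id, condition name, seed, ...).
    """

    dt: float
    data: np.ndarray
    kind: str
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"sampling interval must be positive, got {self.dt}")
        if self.kind not in _KINDS:
            raise ValueError(f"signal kind must be one of {_KINDS}, got {self.kind!r}")
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 1:
            raise ValueError("trace data must be one-dimensional")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n(self) -> int:
        return int(self.data.size)

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def time(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.n)

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (ms)."""
        i = int(round((t - self.t0) / self.dt))
        return min(max(i, 0), self.n - 1)

    def window(self, t_start: float, t_stop: float) -> np.ndarray:
        """Samples with t_start <= t < t_stop."""
        i0 = max(int(np.ceil((t_start - self.t0) / self.dt - 1e-9)), 0)
        i1 = min(int(np.ceil((t_stop - self.t0) / self.dt - 1e-9)), self.n)
        return self.data[i0:i1]

    def copy(self) -> "Trace":
        return Trace(self.dt, self.data.copy(), self.kind, self.t0, dict(self.meta))
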