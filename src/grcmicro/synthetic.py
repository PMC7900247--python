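"""Ground-truth synthetic traces for validating the analysis operators.

Patch-clamp-like fixtures are generated with known event parameters so every
trace metric can be checked against a closed form: postsynaptic-current
trains built from biexponential kernels plus white Gaussian noise, spike
trains with analytically constructed threshold crossings, and a Monte-Carlo
binomial vesicle-release simulation serving as the stochastic oracle for the
deterministic release recursion.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .presyn import PresynapticParams
from .trace import CURRENT, VOLTAGE, Trace


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic postsynaptic-current train.

    The event kernel is the biexponential
    ``A·(exp(−t/tau_decay) − exp(−t/tau_rise))`` normalized to unit peak, so
    ``amplitude`` is the true per-event peak.  Event times are either an
    explicit list or drawn from a Poisson process at ``rate_hz``.
    """

    amplitude: float = 10.0          # pA (or mV for voltage kernels)
    tau_rise: float = 1.4            # ms
    tau_decay: float = 18.0          # ms
    event_times: list | None = None  # ms; None -> Poisson
    rate_hz: float = 3.1
    noise_sd: float = 0.0
    duration: float = 1000.0         # ms
    dt: float = 0.025                # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the biexponential kernel peak (closed form)."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) * math.log(tau_decay / tau_rise)


def biexp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak biexponential kernel evaluated at times ``t`` (>= 0)."""
    tp = biexp_peak_time(tau_rise, tau_decay)
    norm = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    out = np.where(t >= 0.0,
                   (np.exp(-np.maximum(t, 0.0) / tau_decay)
                    - np.exp(-np.maximum(t, 0.0) / tau_rise)) / norm,
                   0.0)
    return out


def biexp_charge(amplitude: float, tau_rise: float, tau_decay: float) -> float:
    """Analytic area of the unit-peak-normalized kernel times amplitude."""
    tp = biexp_peak_time(tau_rise, tau_decay)
    norm = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    return amplitude * (tau_decay - tau_rise) / norm


def biexp_rise_10_90(tau_rise: float, tau_decay: float,
                     resolution: float = 1e-3) -> float:
    """10–90% rise time of the kernel (root-finding on the closed form)."""
    tp = biexp_peak_time(tau_rise, tau_decay)
    t = np.arange(0.0, tp + resolution, resolution)
    y = biexp_kernel(t, tau_rise, tau_decay)
    t10 = t[np.argmax(y >= 0.1)]
    t90 = t[np.argmax(y >= 0.9)]
    return float(t90 - t10)


def gen_psc_train(spec: SyntheticSpec) -> tuple[Trace, list[dict]]:
    """Synthetic PSC trace plus a ground-truth table.

    Returns
    -------
    trace : Trace
        Sum of biexponential kernels plus Gaussian noise (current, pA).
    truth : list of dict
        Per event: onset time, amplitude, analytic peak time, 10–90% rise,
        charge, and an ``overlapping`` flag for events closer than ``dt``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / spec.dt)) + 1
    t = spec.dt * np.arange(n)
    if spec.event_times is not None:
        events = np.asarray(spec.event_times, dtype=float)
    else:
        # Poisson process by exponential inter-event intervals
        events = []
        t_cur = 0.0
        while True:
            t_cur += rng.exponential(1e3 / spec.rate_hz)
            if t_cur >= spec.duration:
                break
            events.append(t_cur)
        events = np.asarray(events)
    data = np.zeros(n)
    truth = []
    tp = biexp_peak_time(spec.tau_rise, spec.tau_decay)
    r1090 = biexp_rise_10_90(spec.tau_rise, spec.tau_decay)
    q = biexp_charge(spec.amplitude, spec.tau_rise, spec.tau_decay)
    sorted_events = np.sort(events)
    support = int(round(10.0 * spec.tau_decay / spec.dt))  # kernel support
    for k, t0 in enumerate(sorted_events):
        i0 = max(int(np.ceil(t0 / spec.dt - 1e-12)), 0)
        i1 = min(i0 + support, n)
        data[i0:i1] += spec.amplitude * biexp_kernel(
            t[i0:i1] - t0, spec.tau_rise, spec.tau_decay)
        overlapping = bool(
            (k > 0 and t0 - sorted_events[k - 1] < spec.dt)
            or (k + 1 < len(sorted_events) and sorted_events[k + 1] - t0 < spec.dt))
        truth.append({"time_ms": float(t0), "amplitude": spec.amplitude,
                      "peak_time_ms": float(t0 + tp), "rise_10_90_ms": r1090,
                      "charge_pA_ms": q, "overlapping": overlapping})
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=n)
    trace = Trace(spec.dt, data, CURRENT,
                  meta={"generator": "gen_psc_train", "seed": spec.seed})
    return trace, truth


# ------------------------------------------------------------------ spikes

def _spike_template(dt: float, threshold_mV: float, rest_mV: float = -70.0,
                    peak_mV: float = 20.0, dvdt_crit: float = 20.0
                    ) -> np.ndarray:
    """A spike waveform whose dV/dt first exceeds ``dvdt_crit`` exactly at
    ``threshold_mV`` on the upstroke (piecewise-linear construction)."""
    if not rest_mV < threshold_mV < peak_mV:
        raise ValueError("threshold must lie between rest and peak")
    # slow approach below threshold (dV/dt well under the criterion), fast
    # linear upstroke above it, exponential repolarization
    slow_rate = 0.25 * dvdt_crit
    fast_rate = 8.0 * dvdt_crit
    seg1 = np.arange(rest_mV, threshold_mV, slow_rate * dt)
    seg2 = np.arange(threshold_mV, peak_mV, fast_rate * dt)
    t_rep = np.arange(0.0, 12.0, dt)
    seg3 = rest_mV + (peak_mV - rest_mV) * np.exp(-t_rep / 1.2)
    return np.concatenate([seg1, seg2, seg3])


def gen_spike_trace(n_spikes: int, spike_times=None, threshold_mV: float = -50.0,
                    rest_mV: float = -70.0, duration: float = 1000.0,
                    dt: float = 0.025, noise_sd: float = 0.0, seed: int = 0
                    ) -> tuple[Trace, list[dict]]:
    """Voltage trace with constructed spikes of known threshold.

    The template's upstroke crosses the 20 mV/ms detection criterion exactly
    at ``threshold_mV``, giving ground truth for the threshold estimator.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    data = np.full(n, rest_mV)
    template = _spike_template(dt, threshold_mV, rest_mV)
    if spike_times is None:
        if n_spikes > 0:
            spike_times = np.linspace(100.0, duration - 100.0, n_spikes)
        else:
            spike_times = np.array([])
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size != n_spikes:
        raise ValueError("spike_times length must equal n_spikes")
    truth = []
    peak_offset = int(np.argmax(template))
    for t0 in spike_times:
        i0 = int(round(t0 / dt))
        i1 = min(i0 + template.size, n)
        seg = template[:i1 - i0]
        data[i0:i1] = np.maximum(data[i0:i1], seg)
        truth.append({"onset_ms": float(t0),
                      "peak_ms": float((i0 + peak_offset) * dt),
                      "threshold_mV": threshold_mV})
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=n)
    trace = Trace(dt, data, VOLTAGE,
                  meta={"generator": "gen_spike_trace", "seed": seed})
    return trace, truth


# ------------------------------------------------------- stochastic oracle

def stochastic_release_oracle(spike_times, params: PresynapticParams,
                              n_trials: int = 10_000, n_sites: int = 1,
                              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo binomial vesicle simulation.

    Each trial follows one release site through the spike train: the site's
    vesicle is released with probability ``u`` when recovered, then cycles
    through inactive/recovering states with exponentially distributed
    dwell times (``tau_i``, ``tau_rec``).  Facilitation follows the same
    deterministic ``u`` recursion as the mean-field model.  The per-spike
    mean released fraction converges to the deterministic recursion.

    Returns
    -------
    (mean, sem) : per-spike mean released fraction and its standard error.
    """
    if n_trials < 1000:
        raise ValueError("n_trials must be >= 1000 for a usable oracle")
    rng = np.random.default_rng(seed)
    t = np.asarray(spike_times, dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("spike times must be strictly increasing")
    n_spk = t.size
    total = n_trials * n_sites
    # per-site state: 0 recovered, else time at which the site recovers
    recover_at = np.full(total, -np.inf)
    u = 0.0
    released = np.zeros((n_spk, ), dtype=float)
    sems = np.zeros(n_spk)
    for k, tk in enumerate(t):
        u = u * (math.exp(-(tk - t[k - 1]) / params.tau_facil) if k else 1.0)
        if k == 0:
            u = 0.0
        u += params.p * (1.0 - u)
        avail = recover_at <= tk
        fire = avail & (rng.random(total) < u)
        n_fire = int(np.count_nonzero(fire))
        frac = fire.astype(float)
        released[k] = frac.mean()
        sems[k] = frac.std(ddof=1) / math.sqrt(total)
        # released vesicles: inactive dwell then recovery dwell
        dwell = rng.exponential(params.tau_i, n_fire) + \
            rng.exponential(params.tau_rec, n_fire)
        recover_at[fire] = tk + dwell
    return released, sems
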