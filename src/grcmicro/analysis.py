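"""Derived metrics for voltage and current traces.

These operators are applied uniformly to simulated and synthetic traces:
spike detection and per-spike threshold/AHP/width statistics, postsynaptic
current metrics (peak, 10–90% rise, mono-exponential decay, charge,
paired-pulse ratio), EPSP metrics (peak and area over a fixed 50-ms window),
input–output frequency curves, and paired condition comparisons
(mean ± SEM, Student's t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .trace import CURRENT, VOLTAGE, Trace

#: dV/dt criterion for spike threshold (mV/ms); documented constant.
DVDT_THRESHOLD = 20.0
#: Minimum inter-spike separation (refractory merging window), ms.
REFRACTORY_MS = 1.0
#: Peak criterion for counting an upstroke as a spike, mV.
SPIKE_PEAK_MV = -20.0
#: Baseline window preceding the (first) stimulus, ms.
BASELINE_MS = 20.0


class SignalKindError(TypeError):
    """An operator was applied to the wrong signal kind."""


def _require(trace: Trace, kind: str) -> None:
    if trace.kind != kind:
        raise SignalKindError(f"operator requires a {kind} trace, got {trace.kind}")


# ---------------------------------------------------------------- spikes

def detect_spikes(trace: Trace, peak_mV: float = SPIKE_PEAK_MV,
                  refractory_ms: float = REFRACTORY_MS) -> np.ndarray:
    """Spike (peak) times in ms, one per suprathreshold upstroke.

    A truncated spike still rising at the end of the trace is excluded.
    """
    _require(trace, VOLTAGE)
    v = trace.data
    above = v > peak_mV
    times = []
    i = 0
    n = len(v)
    min_gap = max(int(round(refractory_ms / trace.dt)), 1)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j == n and v[n - 1] >= v[n - 2]:
                break  # truncated at trace end
            seg = v[i:j]
            p = i + int(np.argmax(seg))
            if not times or (p - int(round((times[-1] - trace.t0) / trace.dt))) >= min_gap:
                times.append(trace.t0 + p * trace.dt)
            i = j
        else:
            i += 1
    return np.asarray(times)


def spike_threshold(trace: Trace, spike_time: float,
                    dvdt_crit: float = DVDT_THRESHOLD) -> float:
    """Membrane potential at which dV/dt first exceeds the criterion on the
    upstroke preceding the spike peak.  Returns NaN if the criterion is never
    met (undefined threshold)."""
    _require(trace, VOLTAGE)
    v = trace.data
    dv = np.gradient(v, trace.dt)
    p = trace.index_at(spike_time)
    # back up to the start of the suprathreshold upstroke
    j = p
    while j > 0 and dv[j - 1] >= dvdt_crit:
        j -= 1
    if j == p and (p == 0 or dv[p - 1] < dvdt_crit):
        # peak sample itself not preceded by a criterion crossing: scan back
        # through the rising phase for the first crossing
        j = p
        while j > 0 and v[j - 1] < v[j]:
            j -= 1
        seg = dv[j:p + 1]
        hits = np.nonzero(seg >= dvdt_crit)[0]
        if hits.size == 0:
            return float("nan")
        j = j + hits[0]
    # sub-sample interpolation of the criterion crossing
    if j > 0 and dv[j] > dv[j - 1]:
        frac = (dvdt_crit - dv[j - 1]) / (dv[j] - dv[j - 1])
        frac = min(max(frac, 0.0), 1.0)
        return float(v[j - 1] + frac * (v[j] - v[j - 1]))
    return float(v[j])


@dataclass
class SpikeMetrics:
    """Per-trace spike statistics."""

    spike_times: np.ndarray
    thresholds: np.ndarray
    ahp_depths: np.ndarray        # threshold minus post-spike minimum, mV (>0)
    half_widths: np.ndarray       # ms at 50% of (peak - threshold)
    first_spike_delay: float      # ms from stimulus onset; NaN if no spike
    mean_frequency: float         # spikes / analysis window, Hz
    inst_frequencies: np.ndarray  # 1/ISI, Hz

    @property
    def count(self) -> int:
        return int(self.spike_times.size)


def spike_metrics(trace: Trace, stim_onset: float = 0.0,
                  window_ms: float | None = None) -> SpikeMetrics:
    """Spike statistics of a voltage trace.

    ``mean_frequency`` is spike count divided by the analysis window (from
    ``stim_onset`` to trace end unless ``window_ms`` is given).
    """
    _require(trace, VOLTAGE)
    st = detect_spikes(trace)
    v = trace.data
    thr = np.array([spike_threshold(trace, t) for t in st])
    ahp, hw = [], []
    for k, t in enumerate(st):
        p = trace.index_at(t)
        nxt = trace.index_at(st[k + 1]) if k + 1 < len(st) else len(v)
        trough = float(np.min(v[p:nxt])) if nxt > p else float(v[p])
        ahp.append(thr[k] - trough)
        # half width at 50% of (peak - threshold)
        if np.isfinite(thr[k]):
            level = thr[k] + 0.5 * (v[p] - thr[k])
            i0 = p
            while i0 > 0 and v[i0 - 1] > level:
                i0 -= 1
            i1 = p
            while i1 < len(v) - 1 and v[i1 + 1] > level:
                i1 += 1
            hw.append((i1 - i0) * trace.dt)
        else:
            hw.append(float("nan"))
    window = (trace.t0 + trace.duration - stim_onset) if window_ms is None else window_ms
    isi = np.diff(st)
    return SpikeMetrics(
        spike_times=st,
        thresholds=thr,
        ahp_depths=np.asarray(ahp),
        half_widths=np.asarray(hw),
        first_spike_delay=float(st[0] - stim_onset) if st.size else float("nan"),
        mean_frequency=1e3 * st.size / window if window > 0 else float("nan"),
        inst_frequencies=1e3 / isi if isi.size else np.array([]),
    )


# ---------------------------------------------------------------- PSCs

@dataclass
class PscMetrics:
    """Per-event postsynaptic-current metrics (signed peak, outward > 0)."""

    peaks: np.ndarray             # baseline-subtracted peak amplitude, pA
    times_to_peak: np.ndarray     # ms from stimulus
    rise_10_90: np.ndarray        # ms
    decay_tau: float              # mono-exponential tau of the (first) event, ms
    decay_r2: float
    charge: float                 # |area| from first stimulus onset, pA*ms
    ppr: float                    # 2nd/1st peak, NaN if < 2 events
    baseline: float
    fit_failed: bool = False


def _event_peak(x: np.ndarray, outward: bool) -> int:
    return int(np.argmax(x)) if outward else int(np.argmin(x))


def psc_metrics(trace: Trace, stim_times, baseline_ms: float = BASELINE_MS,
                event_window_ms: float | None = None) -> PscMetrics:
    """Peak, kinetics and charge of stimulus-locked postsynaptic currents.

    The baseline is the mean over the ``baseline_ms`` preceding the first
    stimulus.  Event polarity is taken from the largest excursion after the
    first stimulus.  The decay of the last event is fitted with a
    mono-exponential from its peak toward baseline (least squares); the fit
    window ends at the next stimulus or at baseline return, whichever first.
    Charge is the unsigned integral of the baseline-subtracted trace from the
    first stimulus to the end of the trace (baseline return).
    """
    _require(trace, CURRENT)
    stim_times = np.atleast_1d(np.asarray(stim_times, dtype=float))
    if stim_times.size == 0:
        raise ValueError("psc_metrics requires at least one stimulus time")
    i_first = trace.index_at(stim_times[0])
    base = float(np.mean(trace.window(stim_times[0] - baseline_ms, stim_times[0]))) \
        if i_first > 0 else 0.0
    y = trace.data - base
    outward = abs(np.max(y[i_first:])) >= abs(np.min(y[i_first:]))

    peaks, ttp, rise = [], [], []
    bounds = list(stim_times) + [trace.t0 + trace.duration]
    for k, t in enumerate(stim_times):
        i0 = trace.index_at(t)
        i1 = trace.index_at(bounds[k + 1]) if event_window_ms is None \
            else min(trace.index_at(t + event_window_ms), trace.n - 1)
        if i1 <= i0:
            continue
        seg = y[i0:i1 + 1]
        p = _event_peak(seg, outward)
        amp = seg[p]
        peaks.append(amp)
        ttp.append(p * trace.dt)
        # 10-90% rise on the rising limb
        limb = seg[:p + 1]
        a = abs(amp)
        sgn = 1.0 if outward else -1.0
        t10 = np.argmax(sgn * limb >= 0.1 * a) if a > 0 else 0
        t90 = np.argmax(sgn * limb >= 0.9 * a) if a > 0 else 0
        rise.append((t90 - t10) * trace.dt)

    # mono-exponential decay fit on the last event
    tau, r2, failed = float("nan"), float("nan"), False
    if peaks:
        k = len(peaks) - 1
        i0 = trace.index_at(stim_times[k] + ttp[k])
        i1 = trace.n - 1
        seg = y[i0:i1 + 1]
        sgn = 1.0 if outward else -1.0
        w = sgn * seg
        # stop at baseline return (first drop below 5% of peak)
        below = np.nonzero(w < 0.05 * abs(peaks[k]))[0]
        if below.size:
            seg = seg[:below[0] + 1]
        tt = trace.dt * np.arange(len(seg))
        if len(seg) >= 5 and abs(peaks[k]) > 0:
            try:
                popt, _ = optimize.curve_fit(
                    lambda t, a, tau_: a * np.exp(-t / tau_), tt, sgn * seg,
                    p0=(abs(peaks[k]), max(5.0, tt[-1] / 3)),
                    bounds=([0, 1e-3], [np.inf, 1e5]), maxfev=2000)
                tau = float(popt[1])
                resid = sgn * seg - popt[0] * np.exp(-tt / tau)
                ss_tot = float(np.sum((sgn * seg - np.mean(sgn * seg)) ** 2))
                r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
            except RuntimeError:
                failed = True
        else:
            failed = True

    charge = float(np.trapezoid(np.abs(y[i_first:]), dx=trace.dt))
    ppr = float(peaks[1] / peaks[0]) if len(peaks) >= 2 and peaks[0] != 0 else float("nan")
    return PscMetrics(
        peaks=np.asarray(peaks), times_to_peak=np.asarray(ttp),
        rise_10_90=np.asarray(rise), decay_tau=tau, decay_r2=r2,
        charge=charge, ppr=ppr, baseline=base, fit_failed=failed,
    )


# ---------------------------------------------------------------- EPSPs

class SpikeContaminationError(ValueError):
    """EPSP metrics requested on a trace containing a spike."""


@dataclass
class EpspMetrics:
    peak: float        # mV above baseline
    rise_10_90: float  # ms
    area: float        # mV*ms over [onset, onset + 50 ms]


EPSP_AREA_WINDOW_MS = 50.0


def epsp_metrics(trace: Trace, stim_time: float,
                 baseline_ms: float = BASELINE_MS) -> EpspMetrics:
    """Peak and area of a subthreshold EPSP.

    Area is the trapezoidal integral of the baseline-subtracted
    depolarization over the fixed window from stimulus onset to +50 ms.
    Raises :class:`SpikeContaminationError` if a spike is detected in the
    window (the result would not be an EPSP).
    """
    _require(trace, VOLTAGE)
    if detect_spikes(trace).size:
        raise SpikeContaminationError("spike detected; EPSP metrics rejected")
    base = float(np.mean(trace.window(stim_time - baseline_ms, stim_time)))
    y = trace.data - base
    i0 = trace.index_at(stim_time)
    i1 = trace.index_at(stim_time + EPSP_AREA_WINDOW_MS)
    seg = y[i0:i1 + 1]
    p = int(np.argmax(seg))
    amp = float(seg[p])
    limb = seg[:p + 1]
    t10 = np.argmax(limb >= 0.1 * amp) if amp > 0 else 0
    t90 = np.argmax(limb >= 0.9 * amp) if amp > 0 else 0
    return EpspMetrics(
        peak=amp,
        rise_10_90=(t90 - t10) * trace.dt,
        area=float(np.trapezoid(seg, dx=trace.dt)),
    )


# ---------------------------------------------------------------- I/O curve

@dataclass
class IoCurve:
    input_hz: np.ndarray
    output_hz: np.ndarray
    slope: float
    intercept: float


def io_curve(input_hz, output_hz) -> IoCurve:
    """Linear fit of output vs input frequency."""
    x = np.asarray(input_hz, dtype=float)
    y = np.asarray(output_hz, dtype=float)
    if x.shape != y.shape:
        raise ValueError("input and output frequency vectors differ in length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("frequencies must be non-negative")
    if x.size >= 2 and np.ptp(x) > 0:
        slope, intercept = np.polyfit(x, y, 1)
    else:
        slope, intercept = 0.0, float(y.mean()) if y.size else 0.0
    return IoCurve(x, y, float(slope), float(intercept))


# ---------------------------------------------------------------- comparisons

@dataclass
class ConditionComparison:
    metric: str
    control: np.ndarray
    treated: np.ndarray
    percent_change: float          # 100*(treated-control)/|control| of the means
    control_mean: float
    control_sem: float
    treated_mean: float
    treated_sem: float
    t_statistic: float
    p_value: float
    degenerate: bool = False       # zero-variance paired differences


def compare_conditions(control, treated, metric: str = "") -> ConditionComparison:
    """Paired comparison of a metric between conditions.

    Reports the percent change of the means, mean ± SEM per condition, and a
    paired two-sided Student's t-test.  Zero-variance differences make the t
    statistic undefined; the result is flagged degenerate (t = 0, p = NaN for
    identical series).
    """
    c = np.asarray(control, dtype=float)
    s = np.asarray(treated, dtype=float)
    if c.shape != s.shape or c.size < 2:
        raise ValueError("paired series of equal length >= 2 required")
    diff = s - c
    degenerate = bool(np.allclose(diff.std(ddof=1), 0.0))
    if degenerate:
        tstat, p = 0.0, float("nan")
        if not np.allclose(diff, 0.0):
            tstat = float("inf") if diff.mean() > 0 else float("-inf")
    else:
        tstat, p = stats.ttest_rel(s, c)
    cm, sm = float(c.mean()), float(s.mean())
    pc = 100.0 * (sm - cm) / abs(cm) if cm != 0 else float("nan")
    return ConditionComparison(
        metric=metric, control=c, treated=s, percent_change=pc,
        control_mean=cm, control_sem=float(stats.sem(c)),
        treated_mean=sm, treated_sem=float(stats.sem(s)),
        t_statistic=float(tstat), p_value=float(p), degenerate=degenerate,
    )


def percent_change(control: float, treated: float) -> float:
    """100·(treated − control)/|control|."""
    return 100.0 * (treated - control) / abs(control)
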