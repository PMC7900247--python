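"""Figure-level reproduction driver.

``reproduce(figure_id)`` runs the protocols behind one of the simulated
figures, computes the derived metrics, and returns a report with a pass/fail
table against the documented quantitative targets (tolerances included), plus
the metric rows ready to be written as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import epsp_metrics, io_curve, percent_change, psc_metrics
from .circuit import (Circuit, CircuitSpec, intrinsic_summary,
                      run_current_steps, run_epsp_protocol, run_ipsc_protocol,
                      run_pp_frequency_sweep, sweep_summary)
from .conditions import ConfigurationError
from .trace import Trace

FIGURES = ("fig7", "fig8a", "fig8b", "fig8cd")


@dataclass
class Check:
    name: str
    value: float
    target: float | None
    tolerance: float | None
    passed: bool | None


@dataclass
class Report:
    figure: str
    checks: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def add(self, name, value, target=None, tolerance=None):
        passed = None
        if target is not None and tolerance is not None:
            passed = bool(abs(value - target) <= tolerance)
        self.checks.append(Check(name, float(value), target, tolerance, passed))

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks if c.passed is not None)

    def table(self) -> str:
        lines = [f"{'check':42s} {'value':>10s} {'target':>10s} {'tol':>8s} {'pass':>5s}"]
        for c in self.checks:
            tgt = "-" if c.target is None else f"{c.target:.2f}"
            tol = "-" if c.tolerance is None else f"{c.tolerance:.2f}"
            ok = "-" if c.passed is None else ("ok" if c.passed else "FAIL")
            lines.append(f"{c.name:42s} {c.value:10.2f} {tgt:>10s} {tol:>8s} {ok:>5s}")
        return "\n".join(lines)


def _epsp_pair(n_mf, n_goc, inhibition, temperature=30.0):
    out = {}
    for cond in ("control", "sevoflurane"):
        circ = Circuit(CircuitSpec(n_mf, n_goc), cond, temperature)
        res = run_epsp_protocol(circ, inhibition_active=inhibition)
        tr = res.trace
        m0 = res.extras["measure_from_ms"]
        sub = Trace(tr.dt, tr.data[tr.index_at(m0):], "voltage", t0=m0)
        m = epsp_metrics(sub, res.extras["stim_ms"])
        out[cond] = m
    return out


def reproduce_fig7(temperature: float = 30.0) -> Report:
    """Intrinsic excitability: step-current series under control vs the
    anesthetic intrinsic bundle; threshold pair and f-I curves."""
    rep = Report("fig7")
    summaries = {}
    for cond in ("control", "sevoflurane_nap", "sevoflurane_intrinsic"):
        res = run_current_steps(cond, 1.0, 20.0, 1.0, duration=400.0,
                                temperature=temperature)
        summaries[cond] = intrinsic_summary(res)
    ctrl, nap, full = (summaries[c] for c in
                       ("control", "sevoflurane_nap", "sevoflurane_intrinsic"))
    rep.add("control threshold (mV)", ctrl["threshold_mV"], -47.0, 1.5)
    rep.add("anesthetic (Nap) threshold (mV)", nap["threshold_mV"], -54.8, 1.5)
    rep.add("threshold lowered (mV)",
            nap["threshold_mV"] - ctrl["threshold_mV"])
    rep.add("rheobase control (pA)", ctrl["rheobase_pA"])
    rep.add("rheobase anesthetic (pA)", full["rheobase_pA"])
    rep.metrics = summaries
    return rep


def reproduce_fig8a(temperature: float = 30.0) -> Report:
    """Single-stimulus GoC→GrC IPSC percent changes (peak and charge)."""
    rep = Report("fig8a")
    res = {}
    for cond in ("control", "sevoflurane"):
        circ = Circuit(CircuitSpec(1, 1), cond, temperature)
        pr = run_ipsc_protocol(circ, n_pulses=1)
        m = psc_metrics(pr.trace, pr.extras["event_times_ms"])
        res[cond] = m
    dpk = percent_change(res["control"].peaks[0], res["sevoflurane"].peaks[0])
    dq = percent_change(res["control"].charge, res["sevoflurane"].charge)
    rep.add("IPSC peak change (%)", dpk, 46.3, 0.15 * 46.3)
    rep.add("IPSC charge change (%)", dq, 99.6, 0.15 * 99.6)
    rep.metrics = {c: {"peak_pA": float(m.peaks[0]), "charge_pA_ms": m.charge,
                       "decay_tau_ms": m.decay_tau} for c, m in res.items()}
    return rep


def reproduce_fig8b(temperature: float = 30.0) -> Report:
    """EPSP percent changes with and without feedforward inhibition."""
    rep = Report("fig8b")
    with_inh = _epsp_pair(3, 1, True, temperature)
    no_inh = _epsp_pair(1, 0, False, temperature)
    dp_i = percent_change(with_inh["control"].peak, with_inh["sevoflurane"].peak)
    da_i = percent_change(with_inh["control"].area, with_inh["sevoflurane"].area)
    dp_0 = percent_change(no_inh["control"].peak, no_inh["sevoflurane"].peak)
    da_0 = percent_change(no_inh["control"].area, no_inh["sevoflurane"].area)
    rep.add("EPSP peak change, inhibition on (%)", dp_i, -32.4, 0.15 * 32.4)
    rep.add("EPSP area change, inhibition on (%)", da_i, -57.1, 0.15 * 57.1)
    rep.add("EPSP peak change, inhibition off (%)", dp_0, -8.9, 0.15 * 8.9)
    rep.add("EPSP area change, inhibition off (%)", da_0, -10.2, 0.15 * 10.2)
    rep.metrics = {"with_inhibition": {c: vars(m) for c, m in with_inh.items()},
                   "no_inhibition": {c: vars(m) for c, m in no_inh.items()}}
    return rep


def reproduce_fig8cd(freqs=(10, 20, 50, 100, 200), goc_range=(0, 1, 2, 3),
                     n_mf: int = 3, temperature: float = 30.0) -> Report:
    """E/I sweep: first-spike delay, spike counts and I/O slope vs GoC count."""
    rep = Report("fig8cd")
    data = {}
    for cond in ("control", "sevoflurane"):
        for n_goc in goc_range:
            circ = Circuit(CircuitSpec(n_mf, n_goc), cond, temperature)
            pr = run_pp_frequency_sweep(circ, freqs_hz=freqs)
            data[(cond, n_goc)] = sweep_summary(pr)
    for n_goc in goc_range:
        c = data[("control", n_goc)]
        s = data[("sevoflurane", n_goc)]
        d_delay = np.nanmean(s["first_delay_ms"]) - np.nanmean(c["first_delay_ms"])
        d_spikes = int(np.sum(s["n_spikes"]) - np.sum(c["n_spikes"]))
        slope_c = io_curve(c["freq_hz"], c["out_hz"]).slope
        slope_s = io_curve(s["freq_hz"], s["out_hz"]).slope
        rep.add(f"first-spike delay change, {n_goc} GoC (ms)", d_delay)
        rep.add(f"total spike change, {n_goc} GoC", d_spikes)
        rep.add(f"I/O slope control, {n_goc} GoC", slope_c)
        rep.add(f"I/O slope anesthetic, {n_goc} GoC", slope_s)
    rep.metrics = {f"{c}_{g}goc": {k: v.tolist() for k, v in d.items()}
                   for (c, g), d in data.items()}
    return rep


def reproduce(figure_id: str, **kwargs) -> Report:
    """Run the protocols behind a simulated figure and report pass/fail."""
    drivers = {"fig7": reproduce_fig7, "fig8a": reproduce_fig8a,
               "fig8b": reproduce_fig8b, "fig8cd": reproduce_fig8cd}
    if figure_id not in drivers:
        raise ConfigurationError(
            f"unknown figure id {figure_id!r}; valid: {', '.join(FIGURES)}")
    return drivers[figure_id](**kwargs)
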