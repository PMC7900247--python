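"""Trace-analysis operators against closed-form and generator ground truth."""

import numpy as np
import pytest
from scipy import stats

from grcmicro.analysis import (SignalKindError, SpikeContaminationError,
                               compare_conditions, detect_spikes,
                               epsp_metrics, io_curve, percent_change,
                               psc_metrics, spike_metrics)
from grcmicro.synthetic import SyntheticSpec, gen_psc_train, gen_spike_trace
from grcmicro.trace import Trace


class TestSpikeDetection:
    def test_flat_trace_yields_nothing(self):
        tr = Trace(0.025, np.full(20000, -70.0), "voltage")
        assert detect_spikes(tr).size == 0

    def test_truncated_spike_excluded(self):
        tr, _ = gen_spike_trace(1, spike_times=[290.0], duration=292.0, seed=0)
        # the template still rises at trace end -> must not count
        assert detect_spikes(tr).size == 0

    def test_wrong_signal_kind_refused(self):
        tr = Trace(0.025, np.zeros(100), "current")
        with pytest.raises(SignalKindError):
            detect_spikes(tr)
        vtr = Trace(0.025, np.full(100, -70.0), "voltage")
        with pytest.raises(SignalKindError):
            psc_metrics(vtr, [1.0])


class TestPscMetrics:
    def test_tau_recovered_from_noiseless_biexponential(self):
        spec = SyntheticSpec(amplitude=10.0, tau_rise=1.4, tau_decay=18.0,
                             event_times=[50.0], noise_sd=0.0,
                             duration=400.0, seed=0)
        tr, _ = gen_psc_train(spec)
        m = psc_metrics(tr, [50.0])
        assert m.decay_tau == pytest.approx(18.0, rel=0.05)
        assert m.peaks[0] == pytest.approx(10.0, rel=0.01)

    def test_identical_events_give_unit_ppr(self):
        spec = SyntheticSpec(amplitude=8.0, tau_rise=1.0, tau_decay=6.0,
                             event_times=[50.0, 250.0], noise_sd=0.0,
                             duration=500.0, seed=0)
        tr, _ = gen_psc_train(spec)
        m = psc_metrics(tr, [50.0, 250.0])
        assert m.ppr == pytest.approx(1.0, abs=1e-3)

    def test_ramp_rise_time_closed_form(self):
        """A linear 0->peak ramp of duration T has rise_10_90 = 0.8 T."""
        dt = 0.025
        ramp_ms = 5.0
        t = np.arange(0, 200.0, dt)
        y = np.clip((t - 20.0) / ramp_ms, 0.0, 1.0) * 10.0
        y[t > 100.0] = 0.0
        m = psc_metrics(Trace(dt, y, "current"), [20.0])
        assert m.rise_10_90[0] == pytest.approx(0.8 * ramp_ms, abs=2 * dt)

    def test_area_is_linear_and_ppr_scale_invariant(self):
        spec = SyntheticSpec(amplitude=5.0, event_times=[50.0, 120.0],
                             noise_sd=0.0, duration=400.0, seed=0)
        tr, _ = gen_psc_train(spec)
        m1 = psc_metrics(tr, [50.0, 120.0])
        tr3 = Trace(tr.dt, 3.0 * tr.data, tr.kind)
        m3 = psc_metrics(tr3, [50.0, 120.0])
        assert m3.charge == pytest.approx(3.0 * m1.charge, rel=1e-12)
        assert m3.ppr == pytest.approx(m1.ppr, rel=1e-12)

    def test_fit_parameter_recovery_under_noise(self):
        """Median relative tau error < 5% over 200 noisy events, SNR >= 10."""
        rng = np.random.default_rng(42)
        errors = []
        for k in range(200):
            tau = rng.uniform(5.0, 50.0)
            amp = 20.0
            spec = SyntheticSpec(amplitude=amp, tau_rise=1.0, tau_decay=tau,
                                 event_times=[30.0], noise_sd=amp / 10.0,
                                 duration=30.0 + 8 * tau, dt=0.1,
                                 seed=int(rng.integers(2 ** 31)))
            tr, _ = gen_psc_train(spec)
            m = psc_metrics(tr, [30.0])
            errors.append(abs(m.decay_tau - tau) / tau)
        assert np.median(errors) < 0.05


class TestEpspMetrics:
    def test_alpha_function_area_closed_form(self):
        """Alpha-function EPSP: area over [onset, onset+50] matches the
        analytic integral A e [tau - (tau+T) exp(-T/tau)] within 1%."""
        dt = 0.025
        tau, amp, T = 8.0, 5.0, 50.0
        t = np.arange(0.0, 300.0, dt)
        onset = 100.0
        s = np.maximum(t - onset, 0.0)
        v = -65.0 + amp * (s / tau) * np.exp(1.0 - s / tau)
        m = epsp_metrics(Trace(dt, v, "voltage"), onset)
        analytic = amp * np.e * (tau - (tau + T) * np.exp(-T / tau))
        assert m.area == pytest.approx(analytic, rel=0.01)
        assert m.peak == pytest.approx(amp, rel=0.01)

    def test_zero_trace_zero_metrics(self):
        tr = Trace(0.025, np.full(12000, -65.0), "voltage")
        m = epsp_metrics(tr, 100.0)
        assert m.peak == pytest.approx(0.0, abs=1e-9)
        assert m.area == pytest.approx(0.0, abs=1e-6)

    def test_spike_contamination_rejected(self):
        tr, _ = gen_spike_trace(1, spike_times=[150.0], duration=400.0, seed=0)
        with pytest.raises(SpikeContaminationError):
            epsp_metrics(tr, 140.0)


class TestIoCurve:
    def test_zero_output_zero_slope(self):
        c = io_curve([10, 50, 100, 200], [0, 0, 0, 0])
        assert c.slope == 0.0

    def test_two_output_definitions_agree_on_doublets(self):
        """Spike count over a fixed window and mean inverse ISI agree for
        doublet responses by construction of the doublet."""
        window = 100.0
        for isi in (5.0, 10.0, 20.0):
            spikes = np.array([10.0, 10.0 + isi])
            by_count = 1e3 * spikes.size / window
            # with exactly 2 spikes in the window the count-based frequency
            # equals 2/window regardless of ISI; cross-check the ISI route
            inst = 1e3 / np.diff(spikes)
            assert by_count == pytest.approx(2e3 / window)
            assert inst[0] == pytest.approx(1e3 / isi)

    def test_mismatched_vectors_rejected(self):
        with pytest.raises(ValueError):
            io_curve([10, 20], [1.0])


class TestCompareConditions:
    def test_identical_series(self):
        r = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.percent_change == 0.0
        assert r.t_statistic == 0.0
        assert r.degenerate

    def test_three_point_textbook_t(self):
        ctrl = np.array([10.0, 12.0, 11.0])
        trt = np.array([13.0, 15.0, 15.0])
        d = trt - ctrl
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        r = compare_conditions(ctrl, trt)
        assert r.t_statistic == pytest.approx(t_manual, rel=1e-12)
        t_scipy, p_scipy = stats.ttest_rel(trt, ctrl)
        assert r.p_value == pytest.approx(p_scipy, rel=1e-12)

    def test_single_pair_percent_change(self):
        assert percent_change(100.0, 146.3) == pytest.approx(46.3)
        assert percent_change(-10.0, -15.0) == pytest.approx(-50.0)

    def test_mean_sem_reporting(self):
        r = compare_conditions([1.0, 3.0], [2.0, 6.0], metric="demo")
        assert r.control_mean == pytest.approx(2.0)
        assert r.treated_mean == pytest.approx(4.0)
        assert r.percent_change == pytest.approx(100.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [2.0])


class TestSpikeMetricsOnGroundTruth:
    def test_counts_delays_and_frequencies(self):
        tr, truth = gen_spike_trace(4, spike_times=[100, 200, 300, 400.0],
                                    duration=600.0, seed=0)
        sm = spike_metrics(tr, stim_onset=50.0, window_ms=500.0)
        assert sm.count == 4
        assert sm.first_spike_delay == pytest.approx(
            truth[0]["peak_ms"] - 50.0, abs=1.0)
        assert sm.mean_frequency == pytest.approx(4 / 0.5, rel=1e-6)
        assert sm.inst_frequencies == pytest.approx(np.full(3, 10.0), rel=0.05)
        # AHP is measured below threshold by construction of the template
        assert np.all(sm.ahp_depths > 0)
        assert np.all(sm.half_widths > 0)
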