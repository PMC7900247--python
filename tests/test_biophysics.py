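"""Cell assembly, gating invariants, integrator behavior."""

import numpy as np
import pytest

from grcmicro.cell import build_goc, build_grc
from grcmicro.conditions import ConfigurationError, get_condition
from grcmicro.gating import GateSpec
from grcmicro.simulate import Stimulus, integrate
from grcmicro.analysis import detect_spikes, spike_metrics
from grcmicro.trace import Trace


@pytest.fixture(scope="module")
def grc_control():
    return build_grc("control", 30.0)


class TestAssembly:
    def test_printed_densities_control(self, grc_control):
        params = grc_control.params["channels"]
        assert params["na_t"]["density_S_per_cm2"]["hillock"] == pytest.approx(0.03)
        assert params["na_t"]["density_S_per_cm2"]["axon1"] == pytest.approx(0.02)
        assert params["kv"]["density_S_per_cm2"]["hillock"] == pytest.approx(0.003)
        assert params["kir"]["density_S_per_cm2"]["soma"] == pytest.approx(1350e-6)
        assert params["gaba_leak"]["density_S_per_cm2"]["soma"] == pytest.approx(60e-6)
        assert params["na_p"]["kinetics"] == {"a_on": 0.75, "a_off": 0.005}

    def test_printed_densities_anesthetic(self):
        m = build_grc("sevoflurane_intrinsic", 30.0)
        params = m.params["channels"]
        assert params["na_t"]["density_S_per_cm2"]["hillock"] == pytest.approx(0.04)
        assert params["na_t"]["density_S_per_cm2"]["axon1"] == pytest.approx(0.03)
        assert params["kv"]["density_S_per_cm2"]["hillock"] == pytest.approx(0.005)
        assert params["na_p"]["kinetics"] == {"a_on": 1.5, "a_off": 0.05}

    def test_four_dendrites(self, grc_control):
        dends = [c for c in grc_control.compartments if c.role == "dendrite"]
        assert len(dends) == 4

    def test_goc_intrinsics_unchanged_by_anesthetic(self):
        ctrl = build_goc("control", 30.0)
        sevo = build_goc("sevoflurane", 30.0)
        assert ctrl.params["channels"] == sevo.params["channels"]

    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigurationError):
            build_grc("desflurane", 30.0)

    def test_temperature_range_enforced(self):
        with pytest.raises(ConfigurationError):
            build_grc("control", 50.0)

    def test_bad_override_key_rejected(self):
        from grcmicro.conditions import ConditionSet
        cond = ConditionSet(name="bad", intrinsic={"grc": {"channels.na_t.bogus": 1}})
        with pytest.raises(ConfigurationError):
            build_grc(cond, 30.0)


class TestGatingInvariants:
    def test_all_gates_valid_over_physiological_range(self, grc_control):
        v = np.linspace(-100, 60, 500)
        for ch in grc_control.channels:
            for g in ch.gates:
                xinf, tau = g.curves(v, rate_factor=ch.rate_factor)
                assert np.all((xinf >= 0) & (xinf <= 1))
                assert np.all(tau > 0)
                assert np.all(np.isfinite(xinf)) and np.all(np.isfinite(tau))

    def test_unknown_gate_form_rejected(self):
        with pytest.raises(ValueError):
            GateSpec("x", "nope", {}).curves(np.array([0.0]))


class TestResting:
    def test_rest_within_one_mV_of_target(self, grc_control):
        tr = integrate(grc_control, Stimulus.zero(), duration=500.0, dt=0.025)
        assert abs(tr.data[-1] + 70.0) < 1.0
        assert detect_spikes(tr).size == 0
        assert np.ptp(tr.data[int(100 / 0.025):]) < 1.0  # flat after settle

    def test_every_condition_rests_quietly(self):
        for cond in ("sevoflurane_nap", "sevoflurane_intrinsic", "sevoflurane"):
            m = build_grc(cond, 30.0)
            tr = integrate(m, Stimulus.zero(), duration=400.0, dt=0.025)
            assert abs(tr.data[-1] + 70.0) < 1.0
            assert detect_spikes(tr).size == 0

    def test_gating_bounds_asserted_in_debug_mode(self, grc_control):
        integrate(grc_control, Stimulus.step(10.0, 20.0, 120.0),
                  duration=150.0, dt=0.025, debug_checks=True)


class TestVoltageClamp:
    def test_clamp_current_settles_to_constant(self, grc_control):
        tr = integrate(grc_control, None, duration=500.0, dt=0.025,
                       mode="voltage-clamp", holding=-70.0)
        late = tr.data[int(100 / 0.025):]
        assert np.ptp(late) < 1.0  # < 1 pA drift over the last 400 ms

    def test_clamp_requires_holding(self, grc_control):
        with pytest.raises(ValueError):
            integrate(grc_control, None, duration=10.0, mode="voltage-clamp")


class TestIntegrator:
    def test_dt_cap_enforced(self, grc_control):
        with pytest.raises(ValueError):
            integrate(grc_control, Stimulus.zero(), duration=10.0, dt=0.1)

    def test_convergence_under_dt_halving(self, grc_control):
        """Spike count identical and spike times shift < 0.1 ms at dt/2."""
        stim = Stimulus.step(12.0, 50.0, 350.0)
        t_ref = None
        for dt in (0.025, 0.0125):
            tr = integrate(grc_control, stim, duration=400.0, dt=dt)
            st = detect_spikes(tr)
            if t_ref is None:
                t_ref = st
            else:
                assert st.size == t_ref.size
                assert np.max(np.abs(st - t_ref)) < 0.1


class TestGoC:
    def test_rests_at_minus_sixty(self):
        goc = build_goc("control", 30.0)
        tr = integrate(goc, Stimulus.zero(), duration=300.0, dt=0.025)
        assert abs(tr.data[-1] + 60.0) < 1.5
        assert detect_spikes(tr).size == 0

    def test_step_current_elicits_prompt_spike(self):
        goc = build_goc("control", 30.0)
        tr = integrate(goc, Stimulus.step(50.0, 20.0, 120.0),
                       duration=150.0, dt=0.025)
        sm = spike_metrics(tr, stim_onset=20.0)
        assert sm.count >= 1
        assert sm.first_spike_delay < 5.0
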