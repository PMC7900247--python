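"""Multi-state receptor kinetics, Mg block and synapse assembly."""

import math

import numpy as np
import pytest

from grcmicro.conditions import ConfigurationError
from grcmicro.receptors import (MG_BLOCK_K_MM, MG_BLOCK_V0_MV, ReceptorScheme,
                                SchemeDefinitionError, mg_block,
                                receptor_current)
from grcmicro.synapse import (build_synapse, clamp_current,
                              synapse_conductances)


class TestMgBlock:
    def test_mg_free_is_unity(self):
        for v in (-100.0, -70.0, -40.0, 0.0, 40.0):
            assert mg_block(v, 0.0) == 1.0

    def test_monotone_in_voltage(self):
        v = np.linspace(-100, 60, 200)
        b = mg_block(v, 1.2)
        assert np.all(np.diff(b) > 0)
        assert mg_block(-70.0, 1.2) < mg_block(-40.0, 1.2)

    def test_closed_form_at_minus40(self):
        expected = 1.0 / (1.0 + (1.2 / MG_BLOCK_K_MM) * math.exp(40.0 / MG_BLOCK_V0_MV))
        assert mg_block(-40.0, 1.2) == pytest.approx(expected, rel=1e-12)

    def test_negative_mg_rejected(self):
        with pytest.raises(ValueError):
            mg_block(-40.0, -0.1)


def _two_state(weight=1.0, erev=0.0, mg=None):
    return ReceptorScheme(
        family="ampa", states=["C", "O"], open_states=["O"],
        transitions=[{"from": "C", "to": "O", "rate": 2.0, "ligand": True},
                     {"from": "O", "to": "C", "rate": 0.5}],
        weight_nS=weight, erev_mV=erev, mg_mM=mg)


class TestScheme:
    def test_zero_transmitter_zero_current(self):
        sch = _two_state()
        conc = np.zeros(2000)
        i = receptor_current(sch, conc, -70.0, 0.025)
        assert np.all(i == 0.0)

    def test_occupancy_conserved_under_pulses(self):
        sch = _two_state()
        conc = np.zeros(8000)
        for t0 in (1000, 3000, 5000):
            conc[t0:t0 + 40] = 1.0
        open_frac = sch.open_fraction(conc, 0.025)  # raises if drifted
        assert np.all(open_frac >= 0) and np.all(open_frac <= 1)

    def test_malformed_schemes_rejected(self):
        with pytest.raises(SchemeDefinitionError):
            ReceptorScheme(family="x", states=["C", "C"], open_states=["C"],
                           transitions=[], weight_nS=1.0, erev_mV=0.0)
        with pytest.raises(SchemeDefinitionError):
            ReceptorScheme(family="x", states=["C", "O"], open_states=["Q"],
                           transitions=[], weight_nS=1.0, erev_mV=0.0)

    def test_inward_at_hyperpolarized_outward_above_reversal(self):
        sch = _two_state(erev=0.0)
        conc = np.zeros(4000)
        conc[400:440] = 1.0
        assert receptor_current(sch, conc, -70.0, 0.025).min() < 0
        assert receptor_current(sch, conc, 40.0, 0.025).max() > 0


class TestGabaSynapse:
    def test_outward_at_zero_mv_holding(self):
        """Chloride currents appear as positive deflections at 0 mV because
        the chloride reversal sits near -65 mV."""
        spec = build_synapse("goc_grc", "control")
        gs, _, _ = synapse_conductances(spec, [20.0], 120.0, 0.025)
        i = clamp_current(gs, 0.0)
        assert i.max() > 0
        assert i.min() >= -1e-12

    def test_repetitive_stimulation_unmasks_slow_tail(self):
        """The glomerular spillover component grows with repetitive
        stimulation: the late tail after a 5-pulse train exceeds the tail of
        a single pulse measured at the same delay after the last event."""
        spec = build_synapse("goc_grc", "control")
        dt = 0.025
        gs1, _, _ = synapse_conductances(spec, [20.0], 400.0, dt)
        train = [20.0, 40.0, 60.0, 80.0, 100.0]
        gs5, _, _ = synapse_conductances(spec, train, 400.0, dt)
        i1 = clamp_current(gs1, -60.0)
        i5 = clamp_current(gs5, -60.0)
        # 80 ms after the last event of each protocol
        t1 = int((20.0 + 1.0 + 80.0) / dt)
        t5 = int((100.0 + 1.0 + 80.0) / dt)
        assert i5[t5] > i1[t1]

    def test_both_receptor_populations_present(self):
        spec = build_synapse("goc_grc", "control")
        names = {r.name for r in spec.receptors}
        assert {"gabaa_a1", "gabaa_a6"} <= names


class TestBuildSynapse:
    def test_control_excitatory_parameters(self):
        spec = build_synapse("mf_grc", "control")
        assert spec.presyn.p == pytest.approx(0.6)
        assert spec.presyn.tau_rec == pytest.approx(8.0)
        assert spec.presyn.tau_facil == pytest.approx(5.0)
        assert spec.presyn.tau_i == pytest.approx(1.0)
        assert spec.presyn.delay == pytest.approx(1.0)

    def test_control_inhibitory_parameters(self):
        spec = build_synapse("goc_grc", "control")
        assert spec.presyn.p == pytest.approx(0.35)
        assert spec.presyn.tau_rec == pytest.approx(36.0)
        assert spec.presyn.tau_facil == pytest.approx(58.5)
        assert spec.presyn.tau_i == pytest.approx(0.1)

    def test_every_class_has_unit_delay(self):
        for kind in ("mf_grc", "mf_goc", "pf_goc", "aa_goc", "goc_grc"):
            assert build_synapse(kind, "control").presyn.delay == 1.0

    def test_anesthetic_removes_nmda_keeps_ampa(self):
        ctrl = build_synapse("mf_grc", "control")
        sevo = build_synapse("mf_grc", "sevoflurane")
        assert sevo.receptor("nmda").scheme.weight_nS == 0.0
        assert sevo.receptor("ampa").scheme.weight_nS == \
            ctrl.receptor("ampa").scheme.weight_nS

    def test_ascending_axon_doubles_parallel_fiber_weights(self):
        pf = build_synapse("pf_goc", "control")
        aa = build_synapse("aa_goc", "control")
        ratio = aa.receptor("ampa").scheme.weight_nS / \
            pf.receptor("ampa").scheme.weight_nS
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_parallel_fiber_release_probability(self):
        assert build_synapse("pf_goc", "control").presyn.p == pytest.approx(0.1)

    def test_kainate_is_slowed_ampa(self):
        pf = build_synapse("pf_goc", "control")
        names = {r.name for r in pf.receptors}
        assert "kainate" in names

    def test_unknown_kind_and_condition_rejected(self):
        with pytest.raises(ConfigurationError):
            build_synapse("mf_purkinje", "control")
        with pytest.raises(ConfigurationError):
            build_synapse("mf_grc", "desflurane")
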