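"""Compartmental solver: closed-form checks, invariants, stimuli, electrodes."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cabletree as ct
from cabletree.morphology import Morphology, soma_cylinder


@pytest.fixture(scope="module")
def soma_only():
    return Morphology([soma_cylinder(np.zeros(3), 20.0)])


class TestParameters:
    def test_tau_accessor(self):
        assert ct.CableParameters(cm=1.0, rm=15000.0).tau == pytest.approx(15.0)

    @pytest.mark.parametrize("kw", [dict(cm=-1.0), dict(rm=0.0), dict(ra=-5.0)])
    def test_nonpositive_rejected(self, kw):
        with pytest.raises(ValueError):
            ct.CableParameters(**kw)


class TestAlphaCurrent:
    def spec(self):
        return ct.StimulusSpec(kind="alpha", location=(1, 0.5),
                               amplitude=1.5, tau0=0.25, tau1=1.0)

    def test_zero_at_origin_and_closed_form_peak(self):
        s = self.spec()
        assert ct.alpha_current(0.0, s) == 0.0
        t = np.linspace(0, 5, 200001)
        t_peak = t[np.argmax(ct.alpha_current(t, s))]
        expect = s.tau0 * s.tau1 * math.log(s.tau1 / s.tau0) / (s.tau1 - s.tau0)
        assert t_peak == pytest.approx(expect, abs=1e-3)
        assert expect == pytest.approx(0.462, abs=1e-3)

    @given(t=st.floats(0.0, 50.0), tau0=st.floats(0.05, 0.9), k=st.floats(1.1, 10.0))
    def test_nonnegative_for_valid_time_constants(self, t, tau0, k):
        s = ct.StimulusSpec(kind="alpha", location=(1, 0.5), amplitude=2.0,
                            tau0=tau0, tau1=k * tau0)
        assert ct.alpha_current(t, s) >= 0.0

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError, match="tau1 > tau0"):
            ct.StimulusSpec(kind="alpha", location=(1, 0.5), tau0=1.0, tau1=0.5)


class TestClosedForms:
    def test_isopotential_rc_charging(self, soma_only, params):
        model = ct.build_model(soma_only, params)
        area_cm2 = soma_only.soma.area * 1e-8
        r_in = params.rm / area_cm2 * 1e-6  # MΩ
        stim = ct.StimulusSpec(kind="step", location=(1, 0.5), amplitude=0.01,
                               delay=0.0, duration=60.0)
        res = ct.simulate(model, [stim], [(1, 0.5)], duration=60.0, dt=0.01)
        theory = 0.01 * r_in * (1 - np.exp(-res.t / params.tau))
        assert np.max(np.abs(res.v[0] - theory)) < 0.005 * theory.max()

    def test_isopotential_input_resistance(self, soma_only, params):
        model = ct.build_model(soma_only, params)
        area_cm2 = soma_only.soma.area * 1e-8
        assert ct.input_resistance(model, (1, 0.5)) == pytest.approx(
            params.rm / area_cm2 * 1e-6, rel=1e-9
        )

    def test_doubling_area_halves_input_resistance(self, params):
        small = Morphology([soma_cylinder(np.zeros(3), 20.0)])
        big = Morphology([soma_cylinder(np.zeros(3), 20.0 * math.sqrt(2.0))])
        r1 = ct.input_resistance(ct.build_model(small, params), (1, 0.5))
        r2 = ct.input_resistance(ct.build_model(big, params), (1, 0.5))
        assert r2 == pytest.approx(r1 / 2.0, rel=1e-9)

    @pytest.mark.parametrize("L", [0.5, 1.0, 2.0])
    def test_sealed_cylinder_coth_formula(self, params, L):
        d = 3.0
        lam = ct.lambda_um(d, params.rm, params.ra)
        m = ct.cylinder_cell(L * lam, d, soma_diam=0.01)
        r = ct.input_resistance(ct.build_model(m, params), (2, 1.0))
        r_inf = (2 / math.pi) * math.sqrt(params.rm * params.ra) * (d * 1e-4) ** -1.5 * 1e-6
        assert r == pytest.approx(r_inf / math.tanh(L), rel=0.01)


class TestSpineCorrection:
    def test_distal_compartments_carry_spine_factor(self, params):
        p = params.with_values(F=1.9, spine_onset=60.0)
        m = ct.cylinder_cell(200.0, 2.0, soma_diam=10.0, sec_type=ct.APICAL)
        plain = ct.build_model(m, params)
        spiny = ct.build_model(m, p)
        prox = plain.comp_path_um < 60.0
        dend = plain.comp_section == 2
        ratio = spiny.c / plain.c
        assert np.allclose(ratio[dend & prox], 1.0)
        assert np.allclose(ratio[dend & ~prox], 1.9)
        gratio = spiny.g_leak / plain.g_leak
        assert np.allclose(gratio[dend & ~prox], 1.9)  # Rm divided by F


class TestSolverInvariants:
    def test_linearity(self, params):
        m = ct.cylinder_cell(400.0, 2.0, soma_diam=15.0)
        model = ct.build_model(m, params)
        probes = [(1, 0.5), (2, 0.9)]

        def run(amp):
            s = ct.StimulusSpec(kind="alpha", location=(2, 0.5), amplitude=amp,
                                tau0=0.25, tau1=1.0)
            return ct.simulate(model, [s], probes, duration=20.0, dt=0.02).v

        v1, v3 = run(1.0), run(3.0)
        assert np.max(np.abs(v3 - 3.0 * v1)) < 1e-9 * np.max(np.abs(v3))

    def test_reciprocity(self, human_cell, params, coarse_policy):
        model = ct.build_model(human_cell[0], params, coarse_policy)
        a, b = (1, 0.5), (2, 0.8)
        s_a = ct.StimulusSpec(kind="alpha", location=a, amplitude=1.5,
                              tau0=0.25, tau1=1.0)
        s_b = ct.StimulusSpec(kind="alpha", location=b, amplitude=1.5,
                              tau0=0.25, tau1=1.0)
        v_ab = ct.simulate(model, [s_a], [b], duration=30.0, dt=0.02).v[0]
        v_ba = ct.simulate(model, [s_b], [a], duration=30.0, dt=0.02).v[0]
        assert np.max(np.abs(v_ab - v_ba)) < 1e-8 * max(np.max(np.abs(v_ab)), 1e-12)

    def test_resting_sections_stay_at_rest(self, params):
        m = ct.cylinder_cell(300.0, 2.0, soma_diam=15.0)
        model = ct.build_model(m, params)
        res = ct.simulate(model, [], [(2, 0.5)], duration=10.0, dt=0.05)
        assert np.max(np.abs(res.v)) == 0.0

    def test_refinement_changes_step_response_below_tenth_mV(self, params):
        m = ct.cylinder_cell(500.0, 2.0, soma_diam=15.0)
        stim = ct.StimulusSpec(kind="step", location=(2, 0.8), amplitude=-0.1,
                               delay=5.0, duration=80.0)
        out = []
        for max_len in (10.0, 5.0):
            model = ct.build_model(m, params, ct.CompartmentPolicy(max_length_um=max_len))
            out.append(ct.simulate(model, [stim], [(1, 0.5)],
                                   duration=100.0, dt=0.02).v[0])
        assert np.max(np.abs(out[0] - out[1])) < 0.1

    def test_latency_converges_with_dt_and_compartments(self, params):
        m = ct.cylinder_cell(600.0, 2.0, soma_diam=15.0)
        site = (2, 0.8)
        stim = ct.StimulusSpec(kind="alpha", location=site, amplitude=1.5,
                               tau0=0.25, tau1=1.0)
        lat = []
        for max_len, dt in ((10.0, 0.01), (5.0, 0.005)):
            model = ct.build_model(m, params, ct.CompartmentPolicy(max_length_um=max_len))
            res = ct.simulate(model, [stim], [ct.Probe(site, label="s"),
                                              ct.Probe((1, 0.5), label="o")],
                              duration=40.0, dt=dt, out_dt=0.01)
            lat.append(res.peak_time("o") - res.peak_time("s"))
        assert abs(lat[0] - lat[1]) <= 0.01 + 1e-12


class TestElectrode:
    def test_series_resistance_preserves_steady_state(self, params):
        m = ct.cylinder_cell(300.0, 2.0, soma_diam=15.0)
        model = ct.build_model(m, params)
        stim = ct.StimulusSpec(kind="step", location=(2, 0.5), amplitude=-0.1,
                               delay=5.0, duration=150.0)
        bare = ct.simulate(model, [stim], [ct.Probe((2, 0.9), label="p")],
                           duration=160.0, dt=0.05)
        wired = ct.simulate(model, [stim],
                            [ct.Probe((2, 0.9), rs=100.0, label="p")],
                            duration=160.0, dt=0.05)
        # no steady current flows into the ideal amplifier: plateau equal
        i_plateau = np.searchsorted(bare.t, 150.0)
        assert wired.v[0, i_plateau] == pytest.approx(bare.v[0, i_plateau], rel=1e-4)
        # but the electrode RC does distort the early transient
        i_early = np.searchsorted(bare.t, 5.6)
        assert not np.allclose(wired.v[0, :i_early], bare.v[0, :i_early], atol=1e-6)


class TestErrors:
    def test_probe_off_tree(self, params):
        m = ct.cylinder_cell(100.0, 2.0)
        model = ct.build_model(m, params)
        stim = ct.StimulusSpec(kind="step", location=(2, 0.5), amplitude=0.1,
                               delay=0.0, duration=5.0)
        with pytest.raises(ct.MorphologyError, match="unknown section"):
            ct.simulate(model, [stim], [(99, 0.5)], duration=10.0, dt=0.05)

    def test_stimulus_longer_than_record_rejected(self, params):
        m = ct.cylinder_cell(100.0, 2.0)
        model = ct.build_model(m, params)
        stim = ct.StimulusSpec(kind="step", location=(2, 0.5), amplitude=0.1,
                               delay=0.0, duration=50.0)
        with pytest.raises(ValueError, match="beyond"):
            ct.simulate(model, [stim], [(2, 0.5)], duration=10.0, dt=0.05)
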