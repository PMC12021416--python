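"""Trace-feature estimators: onset, bAP, axonal velocity, patch Cm, EM thickness."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cabletree as ct

RATE = 15000.0
DT = 1000.0 / RATE


def ramp_epsp_trace(t0=12.0, slope=0.8, duration=40.0, baseline=-70.0):
    """Flat baseline then a linear ramp starting exactly at t0."""
    t = np.arange(int(duration * RATE / 1000.0)) * DT
    v = baseline + np.where(t >= t0, slope * (t - t0), 0.0)
    return ct.Trace(v, RATE), t0


class TestEPSPOnset:
    def test_linear_ramp_onset_exact(self):
        tr, t0 = ramp_epsp_trace()
        onset = ct.detect_epsp_onset(tr, pre_ap_peak=10.0)
        assert onset == pytest.approx(t0, abs=DT)

    def test_shift_equivariance(self):
        tr, t0 = ramp_epsp_trace()
        onset = ct.detect_epsp_onset(tr, 10.0)
        shifted = ct.detect_epsp_onset(tr.shifted(3.5), 13.5)
        assert shifted == pytest.approx(onset + 3.5, abs=1e-9)

    @given(gain=st.floats(0.2, 20.0))
    def test_amplitude_scale_invariance(self, gain):
        tr, t0 = ramp_epsp_trace()
        scaled = ct.Trace(-70.0 + gain * (tr.samples + 70.0), RATE)
        assert ct.detect_epsp_onset(scaled, 10.0) == pytest.approx(
            ct.detect_epsp_onset(tr, 10.0), abs=1e-6)

    def test_flat_trace_raises_no_epsp(self):
        tr = ct.Trace(np.full(600, -70.0), RATE)
        with pytest.raises(ct.FeatureError, match="noise floor"):
            ct.detect_epsp_onset(tr, 10.0)

    def test_step_rise_too_fast_for_band(self):
        t = np.arange(600) * DT
        v = -70.0 + np.where(t >= 20.0, 2.0, 0.0)  # instantaneous rise
        with pytest.raises(ct.FeatureError, match="rising phase"):
            ct.detect_epsp_onset(ct.Trace(v, RATE), 10.0)

    def test_round_trip_with_generator(self):
        pre, post, truth = ct.generate_paired_epsp_traces(1.0, seed=1)
        lat = ct.synaptic_latency(post, pre.ap_peaks[0])
        assert lat == pytest.approx(1.0, abs=DT)

    def test_noisy_sweeps_average_within_tenth_ms(self):
        """Per-sweep delays at σ=0.05 mV scatter; their mean (the reported
        per-cell statistic) recovers the true latency within 0.1 ms."""
        delays = []
        for seed in range(10):
            pre, post, _ = ct.generate_paired_epsp_traces(
                1.1, noise_sigma_mV=0.05, seed=seed)
            try:
                delays.append(ct.synaptic_latency(post, pre.ap_peaks[0]))
            except ct.FeatureError:
                continue
        assert len(delays) >= 8
        assert np.mean(delays) == pytest.approx(1.1, abs=0.1)


class TestBAP:
    @staticmethod
    def ap(t0, n=300, sigma=0.15):
        t = np.arange(n) * DT
        return ct.Trace(-70.0 + 110.0 * np.exp(-((t - t0) ** 2) / (2 * sigma**2)), RATE)

    def test_constructed_shift(self):
        # peaks placed on the sample grid: 5.0 and 5.0 + 7.5 samples = 0.5 ms
        lat, speed = ct.bap_latency_and_speed(
            self.ap(75 * DT), self.ap(75 * DT + 0.5), 150.0)
        assert lat == pytest.approx(0.5, abs=DT)
        assert speed == pytest.approx(0.3, rel=0.15)

    def test_zero_shift_rejected(self):
        with pytest.raises(ct.FeatureError, match="non-positive"):
            ct.bap_latency_and_speed(self.ap(5.0), self.ap(5.0), 150.0)

    def test_noisy_sweep_averaging(self):
        rng = np.random.default_rng(0)
        true = 6 * DT  # 0.4 ms on the sample grid
        soma, dend = [], []
        for _ in range(100):
            s, d = self.ap(75 * DT), self.ap(75 * DT + true)
            soma.append(ct.Trace(s.samples + rng.normal(0, 0.1, len(s.samples)), RATE))
            dend.append(ct.Trace(d.samples + rng.normal(0, 0.1, len(d.samples)), RATE))
        lat, _ = ct.bap_latency_and_speed(soma, dend, 120.0)
        assert lat == pytest.approx(true, abs=DT)


class TestAxonalVelocity:
    def test_zero_ais_reduces_to_naive_ratio(self):
        m = ct.AxonBlebMeasurement(300.0, 0.4, ais_um=0.0)
        naive = 300.0 / 0.4 * 1e-3
        assert ct.correct_axonal_velocity(m) == pytest.approx(naive)
        assert ct.correct_axonal_velocity(m, literal=True) == pytest.approx(naive)

    def test_published_mean_inputs(self):
        # cohort-mean axonal distance and latency
        m = ct.AxonBlebMeasurement(268.203, 0.333, ais_um=35.0)
        assert ct.correct_axonal_velocity(m) == pytest.approx(0.595, abs=0.001)
        assert ct.correct_axonal_velocity(m, literal=True) == pytest.approx(0.713, abs=0.001)

    @given(t=st.floats(0.1, 2.0))
    def test_monotone_decreasing_in_latency(self, t):
        v1 = ct.correct_axonal_velocity(ct.AxonBlebMeasurement(268.0, t, 35.0))
        v2 = ct.correct_axonal_velocity(ct.AxonBlebMeasurement(268.0, t + 0.1, 35.0))
        assert v2 < v1

    def test_unphysical_ais_rejected(self):
        with pytest.raises(ValueError, match="ais < l/2"):
            ct.correct_axonal_velocity(ct.AxonBlebMeasurement(60.0, 0.3, 35.0))


class TestNucleatedPatch:
    def test_surface_formula(self):
        assert ct.patch_surface_um2(10.0, 10.0) == pytest.approx(np.pi * 100.0)

    def test_rc_transient_recovers_capacitance(self):
        rate = 1.0e6  # fast acquisition so the charge integral is accurate
        t = np.arange(0, 2.0, 1000.0 / rate)
        rs, c_pF, dv = 10.0, 1.0, 5.0  # MΩ, pF, mV; tau = 10 µs
        i_pA = dv / rs * np.exp(-t / (rs * c_pF * 1e-3)) * 1000.0
        meas = ct.NucleatedPatchMeasurement(10.0, 10.0, [i_pA],
                                            [np.zeros_like(i_pA)], rate=rate)
        out = ct.nucleated_patch_cm(meas, dv)
        assert out["c_pF"] == pytest.approx(c_pF, rel=0.01)
        assert out["c_exp_pF"] == pytest.approx(c_pF, rel=0.02)
        assert out["cm_uF_per_cm2"] == pytest.approx(c_pF / (np.pi * 100) * 100, rel=0.01)

    def test_residual_identity_gives_zero(self):
        t = np.arange(0, 2.0, 0.005)
        i_pA = 400.0 * np.exp(-t / 0.02)
        meas = ct.NucleatedPatchMeasurement(8.0, 12.0, [i_pA], [i_pA], rate=200000.0)
        assert ct.nucleated_patch_cm(meas, 5.0)["c_pF"] == pytest.approx(0.0, abs=1e-12)

    def test_unsettled_transient_rejected(self):
        i_pA = np.full(200, 50.0)  # never decays
        meas = ct.NucleatedPatchMeasurement(8.0, 12.0, [i_pA],
                                            [np.zeros(200)], rate=200000.0)
        with pytest.raises(ct.FeatureError, match="settle"):
            ct.nucleated_patch_cm(meas, 5.0)


class TestMembraneThickness:
    def test_two_edge_profile(self):
        prof, _ = ct.generate_em_profile(4.2, spacing_nm=0.1, seed=0)
        assert ct.membrane_thickness(prof) == pytest.approx(4.2, abs=0.1)

    def test_flat_profile_raises(self):
        prof = ct.EMLineProfile(np.full(100, 120.0), spacing_nm=0.1)
        with pytest.raises(ct.FeatureError, match="no membrane edge"):
            ct.membrane_thickness(prof)

    def test_shift_of_profile_position_irrelevant(self):
        a, _ = ct.generate_em_profile(4.0, margin_nm=10.0, seed=0)
        b, _ = ct.generate_em_profile(4.0, margin_nm=25.0, seed=0)
        assert ct.membrane_thickness(a) == ct.membrane_thickness(b)
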