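"""Feature extraction from electrophysiological traces and EM line profiles.

Implements the bespoke estimators used on paired-recording data:

* EPSP onset by the two-line method — one line fit to the 1 ms baseline
  around the presynaptic AP peak, one to the 5–30% rising phase; their
  intersection, projected onto the time axis, is the onset.  Synaptic
  latency is onset − presynaptic AP peak time.
* bAP latency and propagation speed from averaged first-AP sweeps at a
  somatic and a dendritic electrode.
* Axonal AP velocity with AIS correction: the AP initiates at the axon
  initial segment (default 35 µm from the hillock) and propagates both ways
  at one speed, so the soma→bleb delay spans (l − 2·ais) of axon.
* Nucleated-patch specific membrane capacitance from capacitive transients
  (charge / voltage-step, residual-subtracted, cross-checked against a
  single-exponential fit), with the patch surface A = π·((a+b)/2)².
* Membrane thickness from an EM intensity line profile: distance between the
  first and last points whose gradient magnitude exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class FeatureError(ValueError):
    """Trace does not contain the feature the estimator looks for."""


@dataclass
class Trace:
    """Uniformly sampled signal (mV or pA) with optional AP-peak annotations."""

    samples: np.ndarray
    rate: float = 15000.0  # Hz
    t0: float = 0.0  # ms
    ap_peaks: list[float] = field(default_factory=list)  # ms

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def t_ms(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) * 1000.0 / self.rate

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate

    def shifted(self, delta_ms: float) -> "Trace":
        return Trace(self.samples.copy(), self.rate, self.t0 + delta_ms,
                     [t + delta_ms for t in self.ap_peaks])


def average_traces(traces: list[Trace]) -> Trace:
    """Pointwise mean of equally sampled sweeps (truncated to shortest)."""
    if not traces:
        raise ValueError("no traces to average")
    rate = traces[0].rate
    if any(tr.rate != rate for tr in traces):
        raise ValueError("sweeps have mismatched sampling rates")
    n = min(len(tr.samples) for tr in traces)
    v = np.mean([tr.samples[:n] for tr in traces], axis=0)
    return Trace(v, rate, traces[0].t0, list(traces[0].ap_peaks))


# ---------------------------------------------------------------------------
# EPSP onset (two-line method)
# ---------------------------------------------------------------------------

def detect_epsp_onset(
    post: Trace,
    pre_ap_peak: float,
    search_window_ms: float = 10.0,
    rise_band: tuple[float, float] = (0.05, 0.30),
) -> float:
    """EPSP onset time (ms) in a postsynaptic trace.

    Line 1 is fit to the baseline from −0.5 to +0.5 ms around the
    presynaptic AP peak; line 2 to the samples between ``rise_band`` (5–30%)
    of the EPSP amplitude, measured from the baseline line to the EPSP peak.
    The onset is the time of their intersection.
    """
    t, v = post.t_ms, post.samples
    base = (t >= pre_ap_peak - 0.5) & (t <= pre_ap_peak + 0.5)
    if base.sum() < 3:
        raise FeatureError("trace too short for the 1 ms baseline window")
    a1, b1 = np.polyfit(t[base], v[base], 1)

    rel = v - (a1 * t + b1)
    search = (t > pre_ap_peak + 0.5) & (t <= pre_ap_peak + search_window_ms)
    if not search.any():
        raise FeatureError("no samples after the baseline window")
    # peak and amplitude from a lightly smoothed deflection (~0.2 ms box) so
    # single noisy samples do not set the 5-30% band; line fits stay raw
    w = max(1, int(round(0.2 * post.rate / 1000.0)))
    rel_s = np.convolve(rel, np.ones(w) / w, mode="same")
    i_peak = np.flatnonzero(search)[int(np.argmax(rel_s[search]))]
    amp = rel_s[i_peak]
    noise = max(3.0 * float(np.std(rel[base])), 1e-12)
    if amp <= noise:
        raise FeatureError("no positive deflection above the noise floor")

    lo, hi = rise_band
    # walk back from the peak through the 30% and 5% crossings: the samples
    # between the crossings are the rising-phase band (robust to noise
    # re-entering the band earlier in the baseline)
    i30 = i_peak
    while i30 > 0 and rel_s[i30 - 1] > hi * amp:
        i30 -= 1
    i30 -= 1  # last sample at or below 30%
    i5 = i30
    while i5 > 0 and rel_s[i5] > lo * amp:
        i5 -= 1
    rising = np.arange(i5 + 1, i30 + 1)
    if len(rising) < 3:
        raise FeatureError(
            f"rising phase has {len(rising)} samples in the {lo:.0%}–{hi:.0%} band (need >= 3)"
        )
    a2, b2 = np.polyfit(t[rising], v[rising], 1)
    if a2 <= a1:
        raise FeatureError("rising-phase slope does not exceed baseline slope")
    return float((b1 - b2) / (a2 - a1))


def synaptic_latency(post: Trace, pre_ap_peak: float, **kw) -> float:
    """Synaptic latency (ms): EPSP onset − presynaptic AP peak."""
    return detect_epsp_onset(post, pre_ap_peak, **kw) - pre_ap_peak


# ---------------------------------------------------------------------------
# bAP latency and speed
# ---------------------------------------------------------------------------

def _peak_time(tr: Trace, threshold_mV: float | None) -> float:
    v = tr.samples
    if threshold_mV is not None and v.max() <= threshold_mV:
        raise FeatureError(f"no AP above {threshold_mV} mV in trace")
    return float(tr.t_ms[int(np.argmax(v))])  # first sample attaining the max


def bap_latency_and_speed(
    soma: Trace | list[Trace],
    dend: Trace | list[Trace],
    distance_um: float,
    ap_threshold_mV: float | None = None,
) -> tuple[float, float]:
    """Back-propagating AP latency (ms) and speed (m/s) between two sites.

    Inputs are single traces or lists of first-AP sweeps (averaged here).
    Latency is the dendritic minus somatic peak time of the averaged signal;
    a non-positive latency raises (probes swapped or no propagation).
    """
    s = average_traces(soma) if isinstance(soma, list) else soma
    d = average_traces(dend) if isinstance(dend, list) else dend
    latency = _peak_time(d, ap_threshold_mV) - _peak_time(s, ap_threshold_mV)
    if latency <= 0:
        raise FeatureError(
            f"non-positive bAP latency ({latency:.4f} ms): check probe order"
        )
    return latency, distance_um / latency * 1e-3


# ---------------------------------------------------------------------------
# Axonal velocity with AIS correction
# ---------------------------------------------------------------------------

@dataclass
class AxonBlebMeasurement:
    """Soma-to-axon-bleb distance l (µm), AP peak latency t (ms), AIS position (µm)."""

    l_um: float
    t_ms: float
    ais_um: float = 35.0

    def __post_init__(self) -> None:
        if self.l_um <= 0 or self.t_ms <= 0 or self.ais_um < 0:
            raise ValueError("require l > 0, t > 0, ais >= 0")


def correct_axonal_velocity(meas: AxonBlebMeasurement, literal: bool = False) -> float:
    """AIS-corrected axonal AP velocity (m/s).

    Default (physical reading): the AP starts at the AIS and travels both
    towards the bleb and back to the soma at one speed, so the measured
    soma→bleb delay covers (l − 2·ais): v = (l − 2·ais)/t.  With
    ``literal=True`` the alternative algebraic reading v = l/(t·(1 + ais/l))
    is used.  Both reduce to l/t at ais = 0.
    """
    l, t, ais = meas.l_um, meas.t_ms, meas.ais_um
    if literal:
        return l / (t * (1.0 + ais / l)) * 1e-3
    if ais >= l / 2.0:
        raise ValueError(
            f"AIS position {ais} µm not physical for path {l} µm (need ais < l/2)"
        )
    return (l - 2.0 * ais) / t * 1e-3


# ---------------------------------------------------------------------------
# Nucleated-patch capacitance
# ---------------------------------------------------------------------------

@dataclass
class NucleatedPatchMeasurement:
    """Nucleus diameters (µm) and capacitive/residual current transients (pA)."""

    a_um: float  # shorter diameter
    b_um: float  # longer diameter
    capacitive: list[np.ndarray]
    residual: list[np.ndarray]
    rate: float = 200000.0  # Hz; capacitive transients are fast

    def __post_init__(self) -> None:
        if not (0 < self.a_um <= self.b_um):
            raise ValueError("need 0 < a <= b")
        if not self.capacitive or not self.residual:
            raise ValueError("need at least one capacitive and one residual transient")


def patch_surface_um2(a_um: float, b_um: float) -> float:
    """Membrane surface of the nucleated patch: A = π·((a+b)/2)² (µm²)."""
    return float(np.pi * ((a_um + b_um) / 2.0) ** 2)


def nucleated_patch_cm(
    meas: NucleatedPatchMeasurement, delta_v_mV: float, settle_tol: float = 0.05
) -> dict:
    """Specific membrane capacitance (µF/cm²) from a nucleated patch.

    The residual (pipette-only) transient is subtracted from the averaged
    capacitive transient; total capacitance is the transferred charge divided
    by the voltage step, cross-checked against a single-exponential fit of
    the decay.  Returns a dict with ``cm_uF_per_cm2``, ``c_pF``,
    ``c_exp_pF``, ``tau_us`` and ``area_um2``.
    """
    if delta_v_mV == 0:
        raise ValueError("voltage step must be non-zero")
    area = patch_surface_um2(meas.a_um, meas.b_um)
    n = min(min(len(x) for x in meas.capacitive), min(len(x) for x in meas.residual))
    cap = np.mean([np.asarray(x[:n], float) for x in meas.capacitive], axis=0)
    res = np.mean([np.asarray(x[:n], float) for x in meas.residual], axis=0)
    corr = cap - res
    dt_ms = 1000.0 / meas.rate
    peak = float(np.max(np.abs(corr)))
    tail = np.abs(corr[int(0.9 * n):])
    if peak > 0 and tail.mean() > settle_tol * peak:
        raise FeatureError("capacitive transient does not settle within the record")
    q_fC = float(np.trapezoid(corr, dx=dt_ms))  # pA·ms = fC
    c_pF = q_fC / delta_v_mV  # fC/mV = pF

    # cross-check: single exponential fitted from the transient peak
    c_exp = np.nan
    tau_us = np.nan
    if peak > 0:
        i0 = int(np.argmax(np.abs(corr)))
        y = corr[i0:]
        t = np.arange(len(y)) * dt_ms
        try:
            (amp, tau), _ = curve_fit(
                lambda tt, A, ta: A * np.exp(-tt / ta), t, y,
                p0=(y[0], max(5 * dt_ms, 1e-3)), maxfev=2000,
            )
            q_pre = float(np.trapezoid(corr[: i0 + 1], dx=dt_ms))
            c_exp = (amp * tau + q_pre) / delta_v_mV
            tau_us = tau * 1000.0
        except RuntimeError:  # fit may fail on degenerate transients
            pass
    return {
        "cm_uF_per_cm2": c_pF / area * 100.0,  # 1 pF/µm² = 100 µF/cm²
        "c_pF": c_pF,
        "c_exp_pF": float(c_exp),
        "tau_us": float(tau_us),
        "area_um2": area,
    }


# ---------------------------------------------------------------------------
# EM membrane thickness
# ---------------------------------------------------------------------------

@dataclass
class EMLineProfile:
    """Intensity samples along a measuring line crossing a membrane."""

    intensity: np.ndarray
    spacing_nm: float
    gradient_threshold: float = 50.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        if len(self.intensity) < 3:
            raise ValueError("profile needs at least 3 samples")
        if self.spacing_nm <= 0:
            raise ValueError("sample spacing must be positive")


def membrane_thickness(profile: EMLineProfile) -> float:
    """Membrane thickness (nm) from an intensity line profile.

    The discrete gradient magnitude (central differences, intensity units per
    sample) is thresholded; thickness is the distance between the first and
    last suprathreshold samples.
    """
    grad = np.abs(np.gradient(profile.intensity))
    idx = np.flatnonzero(grad > profile.gradient_threshold)
    if len(idx) == 0:
        raise FeatureError(
            f"no gradient magnitude above {profile.gradient_threshold}; no membrane edge found"
        )
    return float((idx[-1] - idx[0]) * profile.spacing_nm)
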