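"""Seeded synthetic-data generators for every input class of the pipeline.

Real layer-2/3 pyramidal-cell reconstructions and recordings are large and
not redistributable here, so each generator emulates one input class with a
known ground truth:

* :func:`generate_morphology` — stochastic pyramidal-cell-like morphologies
  (apical trunk + obliques + tuft, multi-stem basal tree) whose cohort
  statistics are calibrated to published species morphometrics
  (:data:`HUMAN` / :data:`RAT` presets);
* :func:`generate_dual_electrode_recording` — soma↔dendrite hyperpolarising
  step protocols simulated on a known passive model plus Gaussian noise;
* :func:`generate_paired_epsp_traces` — presynaptic AP / postsynaptic EPSP
  pairs with a known synaptic latency;
* :func:`generate_em_profile` — EM intensity line profiles with a known
  membrane thickness.

Every generator is a pure function of (parameters, seed) and returns its
:class:`GroundTruth` alongside the data, so downstream estimators can be
round-trip tested.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from . import cable
from . import features as ft
from . import fitting as fi
from . import morphology as mo


@dataclass(frozen=True)
class SpeciesPreset:
    """Cohort targets (mean, SD) for one species' L2/3 pyramidal cells."""

    name: str
    total_length_um: tuple[float, float]
    apical_length_um: tuple[float, float]
    horizontal_extent_um: tuple[float, float]
    vertical_extent_um: tuple[float, float]
    trunk_diam_um: tuple[float, float]
    basal_area_um2: tuple[float, float]
    membrane_thickness_nm: tuple[float, float]
    spine_factor: float
    oblique_diam_um: float
    soma_diam_um: float

    @property
    def basal_length_um(self) -> tuple[float, float]:
        """Basal-length targets implied by total − apical (independent marginals)."""
        mt, st = self.total_length_um
        ma, sa = self.apical_length_um
        return mt - ma, float(np.sqrt(max(st**2 - sa**2, 1.0)))


HUMAN = SpeciesPreset(
    name="human",
    total_length_um=(9054.94, 3699.71),
    apical_length_um=(4349.76, 1638.39),
    horizontal_extent_um=(463.17, 119.48),
    vertical_extent_um=(542.58, 146.89),
    trunk_diam_um=(2.272, 0.584),
    basal_area_um2=(23621.0, 7735.0),
    membrane_thickness_nm=(4.271, 0.873),
    spine_factor=1.9,
    oblique_diam_um=0.75,
    soma_diam_um=18.0,
)

RAT = SpeciesPreset(
    name="rat",
    total_length_um=(5162.68, 1237.71),
    apical_length_um=(2592.15, 818.26),
    horizontal_extent_um=(324.79, 80.58),
    vertical_extent_um=(409.99, 102.69),
    trunk_diam_um=(2.032, 0.413),
    basal_area_um2=(9127.0, 2759.0),
    membrane_thickness_nm=(4.122, 0.779),
    spine_factor=1.5,
    oblique_diam_um=0.65,
    soma_diam_um=15.0,
)

PRESETS = {"human": HUMAN, "rat": RAT}

# passive parameter sets fitted per cell in the source study (printed table);
# keys: cell label -> (Cm µF/cm², Rm Ωcm², Ra Ωcm)
FITTED_PARAMS: dict[str, tuple[float, float, float]] = {
    "Human1": (0.65, 19875.0, 298.0),
    "Human2": (0.60, 15672.0, 263.0),
    "Human3": (0.85, 12872.0, 103.0),
    "Human4": (0.77, 21523.0, 209.0),
    "Human5": (0.63, 15570.0, 109.0),
    "Rat1": (0.84, 13110.0, 267.0),
    "Rat2": (1.16, 9084.0, 249.0),
    "Rat3": (1.02, 14497.0, 115.0),
    "Rat4": (1.41, 8527.0, 109.0),
}


def fitted_cable_parameters(cell: str) -> cable.CableParameters:
    """CableParameters for one of the published per-cell fits, with the
    species' spine correction factor."""
    cm, rm, ra = FITTED_PARAMS[cell]
    F = HUMAN.spine_factor if cell.startswith("Human") else RAT.spine_factor
    return cable.CableParameters(cm=cm, rm=rm, ra=ra, F=F)


@dataclass
class GroundTruth:
    """Generating parameters stored alongside every synthetic dataset."""

    kind: str
    values: dict
    warning: str | None = None

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)

        return json.dumps({"kind": self.kind, "values": self.values,
                           "warning": self.warning}, default=_default, indent=1)


# ---------------------------------------------------------------------------
# Morphology generator
# ---------------------------------------------------------------------------

_STEP = 10.0  # µm between generated sample points


def _clipped_normal(rng, mean, sd, lo):
    return float(max(rng.normal(mean, sd), lo))


class _TreeBuilder:
    def __init__(self, soma_diam: float):
        self.sections: list[mo.Section] = [mo.soma_cylinder(np.zeros(3), soma_diam, 1)]
        self.next_id = 2

    def add(self, parent: int, sec_type: str, pts: np.ndarray, diams: np.ndarray) -> int:
        sid = self.next_id
        self.sections.append(mo.Section(sid, sec_type, pts, diams, parent=parent))
        self.next_id += 1
        return sid

    def tip(self, sid: int) -> np.ndarray:
        return self.sections[sid - 1].points[-1]


def _polyline(start, direction, length, rng, jitter=0.25,
              xlim=None, ylim=None) -> np.ndarray:
    """Wiggly polyline of ~_STEP spacing; reflected at box walls."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    n = max(1, int(round(length / _STEP)))
    pts = [np.asarray(start, float)]
    step = length / n
    for _ in range(n):
        if jitter > 0:
            d = d + rng.normal(0.0, jitter, 3) * np.array([1.0, 1.0, 0.3])
            d = d / np.linalg.norm(d)
        nxt = pts[-1] + d * step
        if xlim is not None:
            if nxt[0] < xlim[0] or nxt[0] > xlim[1]:
                d = d * np.array([-1.0, 1.0, 1.0])
                nxt = pts[-1] + d * step
        if ylim is not None:
            if nxt[1] < ylim[0] or nxt[1] > ylim[1]:
                d = d * np.array([1.0, -1.0, 1.0])
                nxt = pts[-1] + d * step
        pts.append(nxt)
    return np.vstack(pts)


def generate_morphology(preset: SpeciesPreset, seed: int) -> tuple[mo.Morphology, GroundTruth]:
    """One synthetic pyramidal-cell morphology drawn from a species preset.

    Per-cell targets (apical/basal length, extents, trunk diameter, basal
    membrane area) are drawn from the preset's normal marginals; the
    geometry then realises them: a tapering apical trunk along +y carrying
    obliques and an apical tuft, and several basal stems around the soma.
    Two "frame" branches pin the horizontal and vertical extents; basal
    diameters are rescaled post hoc so the basal membrane area matches the
    drawn target exactly.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    # one latent size factor per cell: all targets keep their normal
    # marginals but covary (big cells are big in everything), which keeps
    # the implied basal diameter A/(π·L) in a realistic range
    z_size = rng.normal()
    rho = 0.8

    def draw(mean, sd, lo):
        z = rho * z_size + np.sqrt(1.0 - rho**2) * rng.normal()
        return float(max(mean + sd * z, lo))

    L_ap = draw(*preset.apical_length_um, 800.0)
    bl_mean, bl_sd = preset.basal_length_um
    L_ba = draw(bl_mean, bl_sd, 500.0)
    H = draw(*preset.horizontal_extent_um, 150.0)
    V = draw(*preset.vertical_extent_um, 200.0)
    d_t = draw(*preset.trunk_diam_um, 0.8)
    A_b = draw(*preset.basal_area_um2, 3000.0)

    y_apex, y_bot = 0.88 * V, -0.12 * V
    xlim = (-H / 2.0, H / 2.0)
    d_obl = preset.oblique_diam_um
    tb = _TreeBuilder(preset.soma_diam_um)

    # ---- apical trunk (split at oblique attachment points) ---------------
    y_trunk = 0.55 * y_apex
    trunk_len_budget = y_trunk  # trunk is straight in y
    mean_obl_len = 0.35 * H + 60.0
    rest = max(L_ap - trunk_len_budget - (y_apex - y_trunk), 200.0)
    n_obl = max(2, int(round(0.55 * rest / mean_obl_len)))
    attach_y = np.sort(rng.uniform(0.15, 0.95, n_obl)) * y_trunk

    def trunk_diam(y):
        return d_t * (1.3 - 0.6 * np.clip(y / y_trunk, 0, 1))

    trunk_ids = []
    prev_id, prev_y = 1, 0.0
    for ya in list(attach_y) + [y_trunk]:
        seg_len = ya - prev_y
        if seg_len < 1.0:  # merge near-coincident attachment into next piece
            continue
        n = max(1, int(round(seg_len / _STEP)))
        ys = np.linspace(prev_y, ya, n + 1)
        pts = np.column_stack([rng.normal(0, 1.0, n + 1) * 0.0, ys, np.zeros(n + 1)])
        if prev_id == 1:
            pts[0] = np.zeros(3)
        diams = trunk_diam(ys)
        prev_id = tb.add(prev_id, mo.APICAL, pts, diams)
        trunk_ids.append(prev_id)
        prev_y = ya
    trunk_top = prev_id

    # ---- obliques --------------------------------------------------------
    obl_budget = 0.55 * (L_ap - y_trunk - (y_apex - y_trunk))
    obl_parents = trunk_ids[:-1] if len(trunk_ids) > 1 else trunk_ids
    remaining = obl_budget
    # frame obliques pin ±H/2 (horizontal extent)
    for sign, pid in ((1.0, obl_parents[0]), (-1.0, obl_parents[min(1, len(obl_parents) - 1)])):
        start = tb.tip(pid)
        need = abs(sign * H / 2.0 - start[0])
        pts = _polyline(start, [sign, 0.12, 0.0], need / abs(
            np.cos(np.arctan2(0.12, 1.0))), rng, jitter=0.0)
        pts[-1, 0] = sign * H / 2.0  # touch the wall exactly
        tb.add(pid, mo.APICAL, pts, np.full(len(pts), d_obl))
        remaining -= float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    k = 0
    while remaining > 40.0 and obl_parents:
        pid = obl_parents[k % len(obl_parents)]
        length = min(float(rng.uniform(0.6, 1.4) * mean_obl_len), remaining)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        pts = _polyline(tb.tip(pid), [sign, rng.uniform(-0.2, 0.5), rng.normal(0, 0.2)],
                        length, rng, jitter=0.2, xlim=xlim, ylim=(0.0, y_apex))
        tb.add(pid, mo.APICAL, pts, np.full(len(pts), d_obl))
        remaining -= length
        k += 1

    # ---- tuft ------------------------------------------------------------
    tuft_budget = (y_apex - y_trunk) + max(remaining, 0.0) + 0.45 * (
        L_ap - y_trunk - (y_apex - y_trunk)
    )
    # frame branch: straight to the apex (pins the vertical extent)
    apex_pts = _polyline(tb.tip(trunk_top), [0.0, 1.0, 0.0], y_apex - y_trunk,
                         rng, jitter=0.0)
    apex_pts[-1, 1] = y_apex
    apex_id = tb.add(trunk_top, mo.APICAL, apex_pts,
                     np.full(len(apex_pts), d_obl))
    tuft_budget -= y_apex - y_trunk
    tips = [trunk_top, apex_id]
    while tuft_budget > 40.0:
        pid = tips[int(rng.integers(len(tips)))]
        length = min(float(rng.uniform(40.0, 130.0)), tuft_budget)
        direc = [rng.normal(0, 0.8), rng.uniform(0.4, 1.0), rng.normal(0, 0.2)]
        pts = _polyline(tb.tip(pid), direc, length, rng, jitter=0.25,
                        xlim=(0.8 * xlim[0], 0.8 * xlim[1]), ylim=(y_trunk, y_apex))
        nid = tb.add(pid, mo.APICAL, pts, np.full(len(pts), d_obl))
        tips.append(nid)
        tuft_budget -= length

    # ---- basal tree ------------------------------------------------------
    n_stems = int(rng.integers(4, 8))
    basal_budget = L_ba
    basal_ids = []
    # frame stem straight down (pins the lower vertical extent)
    down_pts = _polyline(np.zeros(3), [0.0, -1.0, 0.0], -y_bot, rng, jitter=0.0)
    down_pts[-1, 1] = y_bot
    basal_ids.append(tb.add(1, mo.BASAL, down_pts, np.ones(len(down_pts))))
    basal_budget -= -y_bot
    stem_dirs = [
        [np.cos(a), 0.35 * np.sin(a) - 0.35, rng.normal(0, 0.2)]
        for a in np.linspace(0.15, np.pi - 0.15, n_stems - 1)
    ]
    stems = []
    for direc in stem_dirs:
        length = min(float(rng.uniform(60.0, 140.0)), max(basal_budget, 40.0))
        pts = _polyline(np.zeros(3), direc, length, rng, jitter=0.15,
                        xlim=xlim, ylim=(y_bot, 0.2 * y_apex))
        sid = tb.add(1, mo.BASAL, pts, np.ones(len(pts)))
        stems.append(sid)
        basal_budget -= length
    tips = list(stems) or list(basal_ids)
    while basal_budget > 40.0:
        pid = tips[int(rng.integers(len(tips)))]
        length = min(float(rng.uniform(40.0, 120.0)), basal_budget)
        direc = [rng.normal(0, 1.0), rng.normal(-0.3, 0.6), rng.normal(0, 0.2)]
        if not np.any(direc):
            direc = [1.0, -0.3, 0.0]
        pts = _polyline(tb.tip(pid), direc, length, rng, jitter=0.25,
                        xlim=xlim, ylim=(y_bot, 0.2 * y_apex))
        nid = tb.add(pid, mo.BASAL, pts, np.ones(len(pts)))
        tips.append(nid)
        basal_budget -= length

    # rescale basal diameters so the basal membrane area hits its target
    basal_secs = [s for s in tb.sections if s.type == mo.BASAL]
    basal_len = sum(s.length for s in basal_secs)
    d_basal = float(np.clip(A_b / (np.pi * basal_len), 0.3, 6.0))
    for s in basal_secs:
        s.diams = np.full_like(s.diams, d_basal)

    # short axon stub
    ax_pts = np.column_stack([np.zeros(6), np.linspace(0, -60.0, 6), np.zeros(6)])
    tb.add(1, mo.AXON, ax_pts, np.full(6, 1.0))

    label = f"{preset.name}_synth_{seed}"
    m = mo.Morphology(tb.sections, metadata={"label": label, "species": preset.name,
                                             "seed": int(seed)})
    truth = GroundTruth(
        kind="morphology",
        values=dict(preset=preset.name, seed=int(seed), apical_length_um=L_ap,
                    basal_length_um=L_ba, horizontal_extent_um=H,
                    vertical_extent_um=V, trunk_diam_um=d_t,
                    basal_area_um2=A_b, basal_diam_um=d_basal),
    )
    return m, truth


def generate_cohort(preset: SpeciesPreset, n: int, seed: int) -> list[tuple[mo.Morphology, GroundTruth]]:
    """n independent morphologies with per-cell seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [generate_morphology(preset, int(s)) for s in seeds]


# ---------------------------------------------------------------------------
# Dual-electrode step recordings
# ---------------------------------------------------------------------------

def generate_dual_electrode_recording(
    m: mo.Morphology,
    p: cable.CableParameters,
    electrode_locations: tuple[tuple[int, float], tuple[int, float]],
    noise_sigma_mV: float = 0.0,
    seed: int | None = None,
    amplitude_nA: float = -0.1,
    step_duration_ms: float = 300.0,
    pre_ms: float = 20.0,
    post_ms: float = 20.0,
    rate: float = 15000.0,
    sim_dt: float = 0.1,
    policy: cable.CompartmentPolicy | None = None,
) -> tuple[fi.RecordingSet, GroundTruth]:
    """Soma↔dendrite step protocols on a known passive model, plus noise.

    For each electrode in turn a current step (default −100 pA, 300 ms) is
    injected and the voltage recorded at both electrodes (four traces),
    sampled at ``rate`` (default 15 kHz) with i.i.d. Gaussian noise of SD
    ``noise_sigma_mV`` added to the voltages.
    """
    if noise_sigma_mV < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    model = cable.build_model(m, p, policy or cable.CompartmentPolicy(max_length_um=10.0))
    duration = pre_ms + step_duration_ms + post_ms
    t_samp = np.arange(int(duration * rate / 1000.0)) * 1000.0 / rate
    traces = []
    for stim_loc in electrode_locations:
        stim = cable.StimulusSpec(kind="step", location=stim_loc,
                                  amplitude=amplitude_nA, delay=pre_ms,
                                  duration=step_duration_ms)
        probes = [cable.Probe(loc, label=str(i))
                  for i, loc in enumerate(electrode_locations)]
        res = cable.simulate(model, [stim], probes, duration=duration,
                             dt=sim_dt, out_dt=sim_dt)
        for i, rec_loc in enumerate(electrode_locations):
            v = np.interp(t_samp, res.t, res.trace(str(i)))
            if noise_sigma_mV > 0:
                v = v + rng.normal(0.0, noise_sigma_mV, len(v))
            traces.append(fi.TraceRecord(stim_loc, rec_loc, stim, v, rate))
    truth = GroundTruth(
        kind="dual_electrode_recording",
        values=dict(cm=p.cm, rm=p.rm, ra=p.ra, F=p.F, spine_onset=p.spine_onset,
                    amplitude_nA=amplitude_nA, step_duration_ms=step_duration_ms,
                    noise_sigma_mV=noise_sigma_mV, rate=rate, seed=seed,
                    electrode_locations=list(map(list, electrode_locations))),
    )
    return fi.RecordingSet(traces, label=m.metadata.get("label", "")), truth


# ---------------------------------------------------------------------------
# Paired AP/EPSP traces
# ---------------------------------------------------------------------------

def generate_paired_epsp_traces(
    latency_ms: float,
    amplitude_mV: float = 1.0,
    noise_sigma_mV: float = 0.0,
    seed: int | None = None,
    rate: float = 15000.0,
    duration_ms: float = 40.0,
    ap_peak_ms: float = 10.0,
    tau_rise_ms: float = 2.0,
    tau_decay_ms: float = 20.0,
) -> tuple[ft.Trace, ft.Trace, GroundTruth]:
    """Presynaptic AP + postsynaptic EPSP pair with a known synaptic latency.

    The presynaptic trace is a narrow AP waveform peaking at ``ap_peak_ms``;
    the postsynaptic EPSP is a difference of exponentials starting exactly
    ``latency_ms`` after the AP peak.  Gaussian noise is added post hoc.
    Returns (pre, post, ground truth); the pre trace carries its AP-peak
    annotation.
    """
    if latency_ms < 0:
        raise ValueError("latency must be >= 0")
    if amplitude_mV <= 0:
        raise ValueError("EPSP amplitude must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration_ms * rate / 1000.0)) * 1000.0 / rate
    pre = -70.0 + 100.0 * np.exp(-((t - ap_peak_ms) ** 2) / (2 * 0.2**2))
    onset = ap_peak_ms + latency_ms
    tt = np.clip(t - onset, 0.0, None)
    shape = np.where(t >= onset,
                     np.exp(-tt / tau_decay_ms) - np.exp(-tt / tau_rise_ms), 0.0)
    peak = shape.max() if shape.max() > 0 else 1.0
    post = -70.0 + amplitude_mV * shape / peak
    if noise_sigma_mV > 0:
        pre = pre + rng.normal(0, noise_sigma_mV, len(t))
        post = post + rng.normal(0, noise_sigma_mV, len(t))
    truth = GroundTruth(
        kind="paired_epsp",
        values=dict(latency_ms=latency_ms, amplitude_mV=amplitude_mV,
                    onset_ms=onset, ap_peak_ms=ap_peak_ms,
                    noise_sigma_mV=noise_sigma_mV, rate=rate, seed=seed),
    )
    return (
        ft.Trace(pre, rate, ap_peaks=[ap_peak_ms]),
        ft.Trace(post, rate),
        truth,
    )


# ---------------------------------------------------------------------------
# EM line profiles
# ---------------------------------------------------------------------------

def generate_em_profile(
    thickness_nm: float,
    edge_contrast: float = 200.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    spacing_nm: float = 0.1,
    margin_nm: float = 10.0,
    threshold: float = 50.0,
) -> tuple[ft.EMLineProfile, GroundTruth]:
    """Two opposing intensity edges separated by a known membrane thickness.

    Intensity drops from ``edge_contrast`` (lumen) to 0 (membrane) across a
    one-sample edge whose midpoint sample carries the half value, so the
    central-difference gradient magnitude peaks exactly at the edge centres
    (value ``edge_contrast``/2).  A contrast too low for the detection
    threshold sets a warning on the ground truth.
    """
    if thickness_nm <= 0:
        raise ValueError("thickness must be positive")
    rng = np.random.default_rng(seed)
    n_margin = int(round(margin_nm / spacing_nm))
    n_thick = max(2, int(round(thickness_nm / spacing_nm)))
    i0 = n_margin
    i1 = i0 + n_thick
    n = i1 + n_margin + 1
    prof = np.full(n, edge_contrast)
    prof[i0 + 1: i1] = 0.0
    prof[i0] = edge_contrast / 2.0
    prof[i1] = edge_contrast / 2.0
    warning = None
    if edge_contrast / 2.0 <= threshold:
        warning = (f"edge gradient {edge_contrast / 2.0} does not exceed "
                   f"threshold {threshold}")
        warnings.warn(warning, stacklevel=2)
    if noise_sigma > 0:
        prof = prof + rng.normal(0, noise_sigma, n)
    truth = GroundTruth(
        kind="em_profile",
        values=dict(thickness_nm=thickness_nm, spacing_nm=spacing_nm,
                    edge_contrast=edge_contrast, noise_sigma=noise_sigma,
                    seed=seed),
        warning=warning,
    )
    return ft.EMLineProfile(prof, spacing_nm, gradient_threshold=threshold), truth


def generate_em_cohort(preset: SpeciesPreset, n: int, seed: int
                       ) -> list[tuple[ft.EMLineProfile, GroundTruth]]:
    """n profiles with thicknesses drawn from the species preset."""
    rng = np.random.default_rng(seed)
    mean, sd = preset.membrane_thickness_nm
    out = []
    for k in range(n):
        th = max(rng.normal(mean, sd), 1.0)
        out.append(generate_em_profile(th, seed=int(rng.integers(0, 2**31 - 1))))
    return out
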