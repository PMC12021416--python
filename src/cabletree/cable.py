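"""Passive branched compartmental cable model with implicit time integration.

The membrane of each compartment is an RC pair (specific capacitance Cm,
resistivity Rm over the compartment's frustum area); compartments are coupled
by axial conductances derived from the specific axial resistivity Ra and the
tapered (frustum) geometry between sample points.  Boundary conditions are
sealed ends.  Dendritic membrane beyond a configurable path distance from the
soma is spine-corrected: Cm·F and Rm/F, accounting for the membrane area of
dendritic spines that are not represented geometrically.

Time integration is Crank–Nicolson (second-order, unconditionally stable);
the system matrix is factorised once per simulation with SuperLU and reused
for every step.  Voltages are relative to rest (passive model: only
deflections matter), so the resting state is identically zero.

An optional recording-electrode model places a series resistance Rs between
the recorded node and an ideal amplifier; a small residual pipette
capacitance on the amplifier side makes Rs distort fast transients while
leaving the steady state at zero current untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import morphology as mo
from .units import CM2_PER_UM2, CM_PER_UM, lambda_um


class SolverError(RuntimeError):
    """Numerical failure inside the cable solver."""


@dataclass(frozen=True)
class CableParameters:
    """Specific passive constants.

    cm: µF/cm²; rm: Ω·cm²; ra: Ω·cm; F: spine correction factor
    (dimensionless, applied as Cm·F and Rm/F); spine_onset: path distance
    (µm) from the soma beyond which F applies.
    """

    cm: float = 1.0
    rm: float = 15000.0
    ra: float = 150.0
    F: float = 1.0
    spine_onset: float = 60.0

    def __post_init__(self) -> None:
        for name in ("cm", "rm", "ra", "F", "spine_onset"):
            if getattr(self, name) < 0 or (name != "spine_onset" and getattr(self, name) <= 0):
                raise ValueError(f"CableParameters.{name} must be positive")

    @property
    def tau(self) -> float:
        """Membrane time constant Rm·Cm in ms."""
        return self.rm * self.cm * 1.0e-3

    def with_values(self, **kw) -> "CableParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class StimulusSpec:
    """Injected-current waveform at a dendritic/somatic location.

    kind: 'step' | 'alpha' | 'ramp' | 'template'.
    location: (section id, arc position in [0, 1]).
    amplitude: step amplitude / alpha A / ramp end amplitude, in nA.
    alpha uses tau0 < tau1 (ms): I(t) = A·(exp(-t/tau1) - exp(-t/tau0)).
    """

    kind: str
    location: tuple[int, float]
    amplitude: float = 0.0
    delay: float = 0.0
    duration: float | None = None
    tau0: float | None = None
    tau1: float | None = None
    template_t: np.ndarray | None = None
    template_i: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("step", "alpha", "ramp", "template"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind in ("step", "ramp"):
            if self.duration is None or self.duration <= 0:
                raise ValueError(f"{self.kind} stimulus requires duration > 0")
        if self.kind == "alpha":
            if self.tau0 is None or self.tau1 is None or not (self.tau1 > self.tau0 > 0):
                raise ValueError("alpha stimulus requires tau1 > tau0 > 0")
        if self.kind == "template":
            if self.template_t is None or self.template_i is None:
                raise ValueError("template stimulus requires template_t and template_i")


def alpha_current(t, spec: StimulusSpec):
    """Alpha-shaped current (nA): A·(e^(−t/τ1) − e^(−t/τ0)), zero for t < 0.

    This transient mimics a fast synaptic current; with the default
    A = 1.5 nA, τ0 = 0.25 ms, τ1 = 1 ms its peak falls at
    t* = τ0·τ1·ln(τ1/τ0)/(τ1−τ0) ≈ 0.46 ms.
    """
    if spec.kind != "alpha":
        raise ValueError("alpha_current requires an alpha StimulusSpec")
    t = np.asarray(t, dtype=float)
    out = np.where(
        t >= 0.0,
        spec.amplitude * (np.exp(-np.clip(t, 0, None) / spec.tau1)
                          - np.exp(-np.clip(t, 0, None) / spec.tau0)),
        0.0,
    )
    return out if out.shape else float(out)


def stimulus_waveform(spec: StimulusSpec, t) -> np.ndarray:
    """Evaluate the stimulus current (nA) at times ``t`` (ms)."""
    t = np.asarray(t, dtype=float)
    tt = t - spec.delay
    if spec.kind == "step":
        return np.where((tt >= 0) & (tt < spec.duration), spec.amplitude, 0.0)
    if spec.kind == "ramp":
        return np.where(
            (tt >= 0) & (tt < spec.duration), spec.amplitude * tt / spec.duration, 0.0
        )
    if spec.kind == "alpha":
        return alpha_current(tt, spec)
    return np.interp(t, spec.template_t, spec.template_i, left=0.0, right=0.0)


@dataclass(frozen=True)
class Probe:
    """Voltage probe at (section, arc); optional series-resistance electrode.

    rs: electrode series resistance in MΩ (None = ideal probe);
    c_pip: residual pipette capacitance on the amplifier side, nF
    (default 0.5 pF — a capacitance-neutralised patch pipette).
    """

    location: tuple[int, float]
    rs: float | None = None
    c_pip: float = 5.0e-4
    label: str | None = None


@dataclass(frozen=True)
class CompartmentPolicy:
    """Spatial discretisation: compartment length min(lambda_fraction·λ, max_length_um)."""

    max_length_um: float = 5.0
    lambda_fraction: float = 0.05


class CompartmentalModel:
    """Assembled passive model: per-compartment capacitance/leak + axial graph."""

    def __init__(self, morph: mo.Morphology, params: CableParameters,
                 policy: CompartmentPolicy):
        self.morphology = morph
        self.params = params
        self.policy = policy
        self._build()

    # -- assembly ----------------------------------------------------------
    def _build(self) -> None:
        m, p = self.morphology, self.params
        c_list: list[float] = []
        g_leak: list[float] = []
        path_um: list[float] = []
        comp_sec: list[int] = []
        comp_arc: list[float] = []
        edges: list[tuple[int, int, float]] = []
        # per-section: (first_comp, ncomp) and distal half-resistance (MΩ)
        self.sec_comps: dict[int, tuple[int, int]] = {}
        attach_comp: dict[int, int] = {}
        attach_halfR: dict[int, float] = {}
        self.collapsed_sections: list[int] = []
        start_dist = mo._section_start_distances(m)

        soma = m.soma
        area = soma.area  # µm²
        c_list.append(p.cm * area * CM2_PER_UM2 * 1.0e3)  # nF
        g_leak.append(area * CM2_PER_UM2 / p.rm * 1.0e6)  # µS
        path_um.append(0.0)
        comp_sec.append(soma.id)
        comp_arc.append(0.5)
        self.sec_comps[soma.id] = (0, 1)
        attach_comp[soma.id] = 0
        d_cm = soma.mean_diam * CM_PER_UM
        l_cm = soma.length * CM_PER_UM
        attach_halfR[soma.id] = 4.0 * p.ra * (l_cm / 2.0) / (math.pi * d_cm**2) * 1.0e-6

        for sec in mo._preorder(m):
            if sec.id == m.root:
                continue
            Lsec = sec.length
            if Lsec <= 0:
                # zero-length section: collapse onto the parent's attachment
                self.collapsed_sections.append(sec.id)
                attach_comp[sec.id] = attach_comp[sec.parent]
                attach_halfR[sec.id] = attach_halfR[sec.parent]
                self.sec_comps[sec.id] = (attach_comp[sec.parent], 0)
                continue
            lam = lambda_um(sec.mean_diam, p.rm, p.ra)
            target = min(self.policy.lambda_fraction * lam, self.policy.max_length_um)
            nseg = max(1, int(math.ceil(Lsec / target)))
            bounds = np.linspace(0.0, Lsec, nseg + 1)
            first = len(c_list)
            prev_halfR = attach_halfR[sec.parent]
            prev_comp = attach_comp[sec.parent]
            spine_types = mo.DENDRITIC_TYPES
            for k in range(nseg):
                s0, s1 = bounds[k], bounds[k + 1]
                a_um2 = _frustum_area(sec, s0, s1)
                r_prox = _axial_R(sec, s0, 0.5 * (s0 + s1), p.ra)
                r_dist = _axial_R(sec, 0.5 * (s0 + s1), s1, p.ra)
                mid_path = start_dist[sec.id] + 0.5 * (s0 + s1)
                F = p.F if (sec.type in spine_types and mid_path >= p.spine_onset) else 1.0
                c_list.append(p.cm * F * a_um2 * CM2_PER_UM2 * 1.0e3)
                g_leak.append(a_um2 * CM2_PER_UM2 / (p.rm / F) * 1.0e6)
                path_um.append(mid_path)
                comp_sec.append(sec.id)
                comp_arc.append(0.5 * (s0 + s1) / Lsec)
                idx = first + k
                edges.append((prev_comp, idx, 1.0 / (prev_halfR + r_prox)))
                prev_comp, prev_halfR = idx, r_dist
            self.sec_comps[sec.id] = (first, nseg)
            attach_comp[sec.id] = prev_comp
            attach_halfR[sec.id] = prev_halfR

        self.n = len(c_list)
        self.c = np.asarray(c_list)
        self.g_leak = np.asarray(g_leak)
        self.comp_path_um = np.asarray(path_um)
        self.comp_section = np.asarray(comp_sec)
        self.comp_arc = np.asarray(comp_arc)
        rows, cols, vals = [], [], []
        for i, j, g in edges:
            rows += [i, j, i, j]
            cols += [j, i, i, j]
            vals += [-g, -g, g, g]
        rows += list(range(self.n))
        cols += list(range(self.n))
        vals += list(self.g_leak)
        self.G = sp.csr_matrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        )

    # -- queries -----------------------------------------------------------
    def locate(self, loc: tuple[int, float]) -> int:
        """Compartment index containing (section, arc)."""
        sid, arc = loc
        if sid not in self.sec_comps:
            raise mo.MorphologyError(f"location references unknown section {sid}")
        first, n = self.sec_comps[sid]
        if n == 0:
            return first
        k = min(int(np.clip(arc, 0.0, 1.0 - 1e-12) * n), n - 1)
        return first + k

    def site_of(self, comp: int) -> tuple[int, float]:
        return int(self.comp_section[comp]), float(self.comp_arc[comp])

    def total_capacitance(self) -> float:
        """Summed membrane capacitance, nF."""
        return float(self.c.sum())


def build_model(
    m: mo.Morphology,
    p: CableParameters,
    policy: CompartmentPolicy | None = None,
) -> CompartmentalModel:
    """Discretise a morphology into a passive compartmental model."""
    return CompartmentalModel(m, p, policy or CompartmentPolicy())


def _interp_diam(sec: mo.Section, s: float) -> float:
    a = sec.arc
    return float(np.interp(s, a, sec.diams))


def _frustum_area(sec: mo.Section, s0: float, s1: float) -> float:
    """Lateral frustum area (µm²) of the section piece [s0, s1] (arc µm)."""
    a = sec.arc
    cuts = [s0] + [float(x) for x in a if s0 < x < s1] + [s1]
    area = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        l = hi - lo
        if l <= 0:
            continue
        r0, r1 = _interp_diam(sec, lo) / 2.0, _interp_diam(sec, hi) / 2.0
        area += math.pi * (r0 + r1) * math.sqrt(l**2 + (r1 - r0) ** 2)
    return area


def _axial_R(sec: mo.Section, s0: float, s1: float, ra: float) -> float:
    """Axial resistance (MΩ) of the piece [s0, s1]; exact for linear taper."""
    a = sec.arc
    cuts = [s0] + [float(x) for x in a if s0 < x < s1] + [s1]
    R = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        l_cm = (hi - lo) * CM_PER_UM
        if l_cm <= 0:
            continue
        d0 = _interp_diam(sec, lo) * CM_PER_UM
        d1 = _interp_diam(sec, hi) * CM_PER_UM
        R += 4.0 * ra * l_cm / (math.pi * d0 * d1)
    return R * 1.0e-6


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Uniformly sampled voltage traces (mV) at named probes."""

    t: np.ndarray  # ms
    v: np.ndarray  # (n_probes, n_t)
    labels: list[str]
    dt: float

    def trace(self, label: str) -> np.ndarray:
        return self.v[self.labels.index(label)]

    def peak_time(self, label: str) -> float:
        """Time of the maximum (first sample attaining it)."""
        y = self.trace(label)
        return float(self.t[int(np.argmax(y))])

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_ms": self.t})
        for lab, row in zip(self.labels, self.v):
            df[lab] = row
        return df

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)


def simulate(
    model: CompartmentalModel,
    stimuli: Sequence[StimulusSpec],
    probes: Sequence[Probe | tuple[int, float]],
    duration: float,
    dt: float = 0.005,
    out_dt: float = 0.01,
    v_init: float = 0.0,
) -> SimulationResult:
    """Integrate the passive system with Crank–Nicolson.

    duration/dt in ms; output is resampled on the coarser ``out_dt`` grid
    (the analysis sampling bin).  Probes with an ``rs`` electrode report the
    pipette-side voltage of the series-resistance model.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    for s in stimuli:
        if s.kind in ("step", "ramp") and s.delay + s.duration > duration + 1e-9:
            raise ValueError("stimulus extends beyond simulation duration")
    probes = [p if isinstance(p, Probe) else Probe(location=p) for p in probes]
    stride = max(1, int(round(out_dt / dt)))

    n = model.n
    n_el = sum(1 for p in probes if p.rs is not None)
    N = n + n_el
    C = np.empty(N)
    C[:n] = model.c
    G = sp.lil_matrix((N, N))
    G[:n, :n] = model.G
    probe_nodes: list[int] = []
    k = n
    for p in probes:
        node = model.locate(p.location)
        if p.rs is None:
            probe_nodes.append(node)
        else:
            g = 1.0 / p.rs  # µS
            G[node, node] += g
            G[k, k] = g
            G[node, k] = -g
            G[k, node] = -g
            C[k] = p.c_pip
            probe_nodes.append(k)
            k += 1
    G = G.tocsr()

    stim_idx = np.array([model.locate(s.location) for s in stimuli], dtype=int)
    nsteps = int(round(duration / dt))
    t_mid = (np.arange(nsteps) + 0.5) * dt
    I_mid = np.zeros((len(stimuli), nsteps))
    for si, s in enumerate(stimuli):
        I_mid[si] = stimulus_waveform(s, t_mid)

    Cdt = sp.diags(C / dt)
    A1 = (Cdt + 0.5 * G).tocsc()
    A2 = (Cdt - 0.5 * G).tocsr()
    lu = spla.splu(A1)

    V = np.full(N, float(v_init))
    nt_out = nsteps // stride + 1
    out = np.empty((len(probes), nt_out))
    out[:, 0] = V[probe_nodes]
    t_out = np.arange(nt_out) * (stride * dt)
    oi = 1
    for step in range(nsteps):
        rhs = A2.dot(V)
        for si in range(len(stimuli)):
            rhs[stim_idx[si]] += I_mid[si, step]
        V = lu.solve(rhs)
        if (step + 1) % stride == 0:
            out[:, oi] = V[probe_nodes]
            oi += 1
    if not np.all(np.isfinite(out)):
        raise SolverError(
            f"non-finite voltages (n={N}, dt={dt}, duration={duration}); "
            "check stimulus amplitudes and geometry"
        )
    labels = [
        p.label or f"sec{p.location[0]}@{p.location[1]:.3f}" for p in probes
    ]
    return SimulationResult(t=t_out, v=out[:, :oi], labels=labels, dt=stride * dt)


def input_resistance(model: CompartmentalModel, loc: tuple[int, float]) -> float:
    """Steady-state input resistance (MΩ) at a location: solve G·V = I directly."""
    idx = model.locate(loc)
    I = np.zeros(model.n)
    I[idx] = 1.0  # nA; the system is linear
    V = spla.spsolve(model.G.tocsc(), I)
    return float(V[idx])  # mV / nA = MΩ
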