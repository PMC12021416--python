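"""Per-cell passive-parameter fitting from dual-electrode step responses.

The three specific constants (Cm, Rm, Ra) are estimated by minimising the
summed squared difference between recorded voltage traces and the passive
model's response to the same current stimuli, across all traces of a
recording set — typically hyperpolarising steps injected at the dendrite and
recorded at the soma and locally, and vice versa.  Cross-location traces
(stimulate one electrode, record at the other) are the most informative: they
constrain Ra, which a soma-only recording leaves weakly determined, and they
avoid the bridge-balance problem of single-electrode recordings.

The optimiser is a bounded derivative-free conjugate-direction search
(Powell), optionally multi-started from seeded random points inside the
bounds.  Spine correction (Cm·F, Rm/F beyond the onset distance) is applied
to every candidate model exactly as in the forward simulations.  The voltage
dependence of hyperpolarisation-activated currents is deliberately not
modelled; fits should use hyperpolarising steps where that nonlinearity is
minimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import cable
from . import morphology as mo

DEFAULT_BOUNDS = {"cm": (0.3, 2.0), "rm": (3000.0, 40000.0), "ra": (50.0, 400.0)}
_SCALES = np.array([1.0, 1.0e4, 1.0e2])  # conditioning scales for (cm, rm, ra)


@dataclass
class TraceRecord:
    """One recorded sweep: stimulus, recording site and sampled voltage."""

    stim_location: tuple[int, float]
    rec_location: tuple[int, float]
    stimulus: cable.StimulusSpec
    voltage: np.ndarray  # mV
    rate: float = 15000.0  # Hz

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(len(self.voltage)) * 1000.0 / self.rate

    def stim_key(self) -> tuple:
        s = self.stimulus
        return (self.stim_location, s.kind, s.amplitude, s.delay, s.duration)


@dataclass
class RecordingSet:
    """Traces from one cell plus the morphology they map onto."""

    traces: list[TraceRecord]
    label: str = ""

    def averaged(self) -> "RecordingSet":
        """Average repetitions of the same (stimulus, recording site) pair."""
        groups: dict[tuple, list[TraceRecord]] = {}
        for tr in self.traces:
            groups.setdefault((tr.stim_key(), tr.rec_location), []).append(tr)
        out = []
        for (_, _), trs in groups.items():
            n = min(len(t.voltage) for t in trs)
            v = np.mean([t.voltage[:n] for t in trs], axis=0)
            first = trs[0]
            out.append(TraceRecord(first.stim_location, first.rec_location,
                                   first.stimulus, v, first.rate))
        return RecordingSet(out, label=self.label)

    def baseline_subtracted(self) -> "RecordingSet":
        """Subtract the mean over the pre-stimulus window from each trace."""
        out = []
        for tr in self.traces:
            pre = tr.t_ms < tr.stimulus.delay
            v = tr.voltage - (tr.voltage[pre].mean() if pre.any() else 0.0)
            out.append(TraceRecord(tr.stim_location, tr.rec_location, tr.stimulus,
                                   v, tr.rate))
        return RecordingSet(out, label=self.label)

    def to_frame(self) -> pd.DataFrame:
        """Wide plain-text layout: one time column + one voltage column per trace."""
        n = max(len(t.voltage) for t in self.traces)
        df = pd.DataFrame({"t_ms": np.arange(n) * 1000.0 / self.traces[0].rate})
        for k, tr in enumerate(self.traces):
            col = np.full(n, np.nan)
            col[: len(tr.voltage)] = tr.voltage
            df[f"v{k}_mV"] = col
        return df


@dataclass
class FitResult:
    """Outcome of a passive-parameter fit."""

    cm: float
    rm: float
    ra: float
    residual_rms_mV: list[float]
    converged: bool
    iterations: int
    n_evaluations: int
    init: cable.CableParameters
    objective_init: float
    objective_final: float
    weak_parameters: list[str] = field(default_factory=list)

    @property
    def parameters(self) -> cable.CableParameters:
        return self.init.with_values(cm=self.cm, rm=self.rm, ra=self.ra)

    @property
    def tau_ms(self) -> float:
        return self.cm * self.rm * 1e-3

    def as_dict(self) -> dict:
        return {
            "cm_uF_per_cm2": self.cm,
            "rm_ohm_cm2": self.rm,
            "ra_ohm_cm": self.ra,
            "tau_ms": self.tau_ms,
            "residual_rms_mV": self.residual_rms_mV,
            "converged": self.converged,
            "iterations": self.iterations,
            "weak_parameters": self.weak_parameters,
        }


class _Forward:
    """Forward model: candidate (Cm, Rm, Ra) -> per-trace model voltages."""

    def __init__(self, m: mo.Morphology, data: RecordingSet,
                 template: cable.CableParameters,
                 policy: cable.CompartmentPolicy | None, sim_dt: float):
        self.m = m
        self.template = template
        self.policy = policy or cable.CompartmentPolicy(max_length_um=10.0)
        self.sim_dt = sim_dt
        # group traces by stimulus so one simulation serves several probes
        self.groups: list[tuple[cable.StimulusSpec, list[TraceRecord]]] = []
        by_key: dict[tuple, list[TraceRecord]] = {}
        for tr in data.traces:
            by_key.setdefault(tr.stim_key(), []).append(tr)
        for trs in by_key.values():
            self.groups.append((trs[0].stimulus, trs))
        for tr in data.traces:
            # fail early on unmappable locations
            mdl_check = (tr.stim_location, tr.rec_location)
            for sid, _ in mdl_check:
                if sid not in m.sections:
                    raise mo.MorphologyError(
                        f"trace references section {sid} absent from morphology"
                    )

    def residuals(self, cm: float, rm: float, ra: float) -> list[np.ndarray]:
        p = self.template.with_values(cm=cm, rm=rm, ra=ra)
        model = cable.build_model(self.m, p, self.policy)
        out = []
        for stim, trs in self.groups:
            duration = max(tr.t_ms[-1] for tr in trs) + self.sim_dt
            probes = [cable.Probe(tr.rec_location, label=str(i))
                      for i, tr in enumerate(trs)]
            res = cable.simulate(model, [stim], probes, duration=duration,
                                 dt=self.sim_dt, out_dt=self.sim_dt)
            for i, tr in enumerate(trs):
                v_model = np.interp(tr.t_ms, res.t, res.trace(str(i)))
                out.append(v_model - tr.voltage)
        return out

    def objective(self, x: np.ndarray) -> float:
        cm, rm, ra = x * _SCALES
        return float(sum(np.sum(r**2) for r in self.residuals(cm, rm, ra)))


def fit_passive_params(
    m: mo.Morphology,
    data: RecordingSet,
    init: cable.CableParameters,
    bounds: dict | None = None,
    seed: int | None = None,
    n_starts: int = 1,
    policy: cable.CompartmentPolicy | None = None,
    sim_dt: float = 0.1,
    maxiter: int = 60,
    xtol: float = 1e-5,
) -> FitResult:
    """Fit (Cm, Rm, Ra) to a recording set by least squares.

    Repetitions are averaged and traces baseline-subtracted before fitting.
    ``init`` provides the starting point and the fixed spine correction
    (F, spine_onset).  Additional seeded random starts inside the bounds
    guard against local minima; the result is deterministic given
    (init, seed, n_starts).  The returned objective never exceeds the
    objective at ``init`` (descent guarantee).  Parameters whose ±20%
    perturbation changes the objective by less than 1% are reported in
    ``weak_parameters`` as practically unidentifiable from these data.
    """
    if not data.traces:
        raise ValueError("recording set is empty")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    prep = data.averaged().baseline_subtracted()
    fwd = _Forward(m, prep, init, policy, sim_dt)

    lo = np.array([bounds["cm"][0], bounds["rm"][0], bounds["ra"][0]]) / _SCALES
    hi = np.array([bounds["cm"][1], bounds["rm"][1], bounds["ra"][1]]) / _SCALES
    x_init = np.array([init.cm, init.rm, init.ra]) / _SCALES
    x_init = np.clip(x_init, lo, hi)
    f_init = fwd.objective(x_init)

    rng = np.random.default_rng(seed)
    starts = [x_init] + [rng.uniform(lo, hi) for _ in range(max(0, n_starts - 1))]

    best = None
    total_nit = total_nfev = 0
    any_converged = False
    for x0 in starts:
        res = minimize(
            fwd.objective, x0, method="Powell",
            bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter, "xtol": xtol, "ftol": 1e-12},
        )
        total_nit += int(res.nit)
        total_nfev += int(res.nfev)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    x_best, f_best = np.asarray(best.x), float(best.fun)
    if f_best > f_init:  # descent guarantee
        x_best, f_best = x_init, f_init

    cm, rm, ra = x_best * _SCALES
    resid = fwd.residuals(cm, rm, ra)
    rms = [float(np.sqrt(np.mean(r**2))) for r in resid]

    # identifiability diagnostic: a parameter whose ±20% perturbation barely
    # moves the objective (relative to the residual, floored at 1% of the
    # data's signal power so a perfect fit still normalises sensibly) is
    # practically unconstrained by these traces
    signal_power = float(sum(np.sum(tr.voltage**2) for tr in prep.traces))
    denom = f_best + 0.01 * signal_power
    weak = []
    for k, name in enumerate(("cm", "rm", "ra")):
        worst = 0.0
        for fac in (0.8, 1.2):
            xp = x_best.copy()
            xp[k] = np.clip(xp[k] * fac, lo[k], hi[k])
            worst = max(worst, abs(fwd.objective(xp) - f_best))
        if worst / denom < 0.01:
            weak.append(name)

    return FitResult(
        cm=float(cm), rm=float(rm), ra=float(ra), residual_rms_mV=rms,
        converged=any_converged, iterations=total_nit, n_evaluations=total_nfev,
        init=init, objective_init=f_init, objective_final=f_best,
        weak_parameters=weak,
    )


def load_trace_table(path) -> pd.DataFrame:
    """Read a plain-text tabular trace export (time column + channel columns)."""
    return pd.read_csv(path, sep=None, engine="python", comment="#")
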