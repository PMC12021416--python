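"""EPSP latency and velocity maps over dendritic trees.

For each dendritic site an alpha-shaped current transient is injected and the
voltage recorded locally and at the soma; the dendrite-to-soma latency is the
difference between the two peak times (on the 0.01 ms analysis grid), and the
velocity is the path distance divided by that latency.  Distances are also
expressed electrotonically (L, in λ units) and times in units of the membrane
time constant τ = Rm·Cm, which collapses the curves of uniform cylinders of
different diameters onto a single master curve; far from boundaries and from
the injection site, the peak velocity converges to 2λ/τ.

The module also implements hybrid-cell latency-grams (per-site latency change
when one cell's basal tree replaces another's) and the ball-and-stick
conductance-load experiment (a family of basal equivalent cylinders loading a
long apical cable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import builders, cable
from . import morphology as mo
from .units import lambda_um

DEFAULT_ALPHA = dict(amplitude=1.5, tau0=0.25, tau1=1.0)
DEFAULT_WINDOW = (27.0, 289.0)


@dataclass
class LatencyMap:
    """Per-site EPSP latency/velocity table plus cell-level metadata.

    Columns of ``table``: section, arc, path_um, L_lambda, latency_ms,
    latency_tau, velocity_m_per_s, velocity_lambda_tau, flagged.
    """

    table: pd.DataFrame
    tau_ms: float
    window: tuple[float, float]

    def valid(self) -> pd.DataFrame:
        return self.table[~self.table.flagged]

    def summary_curve(self, column: str = "latency_ms", grid_um: float = 1.0,
                      half_width_um: float = 5.0) -> pd.DataFrame:
        """Branch-averaged distance profile, smoothed with a rolling window.

        Sites are first averaged per branch (section) on a ``grid_um``
        distance grid, then branches sharing a grid distance are averaged
        with equal weight, then a rolling mean of total width
        ``2·half_width_um`` is applied.
        """
        t = self.valid()
        if t.empty:
            return pd.DataFrame({"path_um": [], column: []})
        g = (t.path_um / grid_um).round().astype(int)
        per_branch = (
            t.assign(gbin=g).groupby(["gbin", "section"])[column].mean().reset_index()
        )
        per_dist = per_branch.groupby("gbin")[column].mean()
        idx = np.arange(per_dist.index.min(), per_dist.index.max() + 1)
        series = per_dist.reindex(idx)
        w = max(1, int(round(2 * half_width_um / grid_um)) + 1)
        smooth = series.rolling(w, center=True, min_periods=1).mean()
        return pd.DataFrame({"path_um": idx * grid_um, column: smooth.values})

    def window_mean(self, column: str = "latency_ms") -> float:
        """Mean of the smoothed summary curve within the distance window."""
        c = self.summary_curve(column)
        lo, hi = self.window
        sel = c[(c.path_um >= lo) & (c.path_um <= hi)][column].dropna()
        if sel.empty:
            raise ValueError(f"no sites inside window {self.window}")
        return float(sel.mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sample_sites(
    model: cable.CompartmentalModel,
    types: tuple[str, ...] = (mo.APICAL,),
    stride: int = 1,
) -> list[tuple[int, float]]:
    """Compartment-midpoint sites on sections of the given types."""
    m = model.morphology
    sites = []
    for i in range(model.n):
        sec = m.sections[int(model.comp_section[i])]
        if sec.type in types:
            sites.append((sec.id, float(model.comp_arc[i])))
    return sites[::stride]


def epsp_latency_map(
    m: mo.Morphology,
    p: cable.CableParameters,
    sites: list[tuple[int, float]] | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    policy: cable.CompartmentPolicy | None = None,
    site_stride: int = 1,
    duration: float = 60.0,
    dt: float = 0.025,
    out_dt: float = 0.01,
    electrode_rs: float | None = None,
    alpha_params: dict | None = None,
) -> LatencyMap:
    """EPSP latency/velocity at dendritic sites of a morphology.

    Injects the alpha current (default A=1.5 nA, τ0=0.25 ms, τ1=1 ms) at each
    site in turn; latency = somatic peak time − local peak time at ``out_dt``
    resolution.  ``electrode_rs`` (MΩ) optionally places a series-resistance
    recording electrode at the dendritic site.  Sites whose local or somatic
    response has no resolvable peak are flagged and excluded from summaries.
    """
    model = cable.build_model(m, p, policy)
    if sites is None:
        sites = sample_sites(model, stride=site_stride)
    if not sites:
        raise ValueError("no dendritic sites to map")
    ap = dict(DEFAULT_ALPHA, **(alpha_params or {}))
    soma_probe = cable.Probe((m.root, 0.5), label="soma")
    rows = []
    for site in sites:
        stim = cable.StimulusSpec(kind="alpha", location=site, **ap)
        site_probe = cable.Probe(site, rs=electrode_rs, label="site")
        res = cable.simulate(model, [stim], [site_probe, soma_probe],
                             duration=duration, dt=dt, out_dt=out_dt)
        dist, L = mo.electrotonic_path(m, site, p)
        flagged = False
        vs, vo = res.trace("site"), res.trace("soma")
        if vs.max() < 1e-6 or vo.max() < 1e-6:
            flagged = True
            latency = np.nan
        else:
            i_s, i_o = int(np.argmax(vs)), int(np.argmax(vo))
            if i_o >= len(vo) - 1:  # somatic peak not reached in record
                flagged = True
            latency = float(res.t[i_o] - res.t[i_s])
        if dist == 0.0:
            latency = 0.0
        vel = dist / latency * 1e-3 if (latency and latency > 0) else np.nan
        lat_tau = latency / p.tau if latency is not None else np.nan
        vel_norm = L / lat_tau if (lat_tau and lat_tau > 0) else np.nan
        rows.append(
            dict(section=site[0], arc=site[1], path_um=dist, L_lambda=L,
                 latency_ms=latency, latency_tau=lat_tau,
                 velocity_m_per_s=vel, velocity_lambda_tau=vel_norm,
                 flagged=flagged)
        )
    return LatencyMap(table=pd.DataFrame(rows), tau_ms=p.tau, window=window)


@dataclass
class LatencyGram:
    """Per-site latency change of a hybrid cell relative to its original."""

    table: pd.DataFrame  # section, arc, path_um, delta_latency_ms

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def latency_gram(original: LatencyMap, hybrid: LatencyMap) -> LatencyGram:
    """Δlatency = hybrid − original, per apical site.

    The two maps must cover identical site sets (the hybrid-cell surgery
    preserves apical section ids, so maps on original and hybrid cells are
    directly comparable).
    """
    key = ["section", "arc"]
    a = original.table.set_index(key)
    b = hybrid.table.set_index(key)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            f"site sets differ; only in original: {list(only_a)[:5]}, "
            f"only in hybrid: {list(only_b)[:5]}"
        )
    merged = a.join(b, lsuffix="_orig", rsuffix="_hyb")
    out = pd.DataFrame(
        {
            "section": [i[0] for i in merged.index],
            "arc": [i[1] for i in merged.index],
            "path_um": merged.path_um_orig.values,
            "delta_latency_ms": (merged.latency_ms_hyb - merged.latency_ms_orig).values,
        }
    )
    return LatencyGram(table=out)


# ---------------------------------------------------------------------------
# Uniform-cable asymptotics and the conductance-load experiment
# ---------------------------------------------------------------------------

def uniform_cable_velocity(
    diam_um: float = 3.0,
    p: cable.CableParameters | None = None,
    length_lambda: float = 10.0,
    probe_lambdas: tuple[float, float] = (4.0, 6.0),
    dt: float = 0.01,
    policy: cable.CompartmentPolicy | None = None,
) -> dict:
    """Asymptotic EPSP peak velocity on a long sealed uniform cable, in λ/τ.

    The alpha transient is injected at the sealed distal tip; velocity is the
    peak-to-peak delay between probes ``probe_lambdas`` away from the
    injection site.  Far from boundaries and the stimulus this converges to
    the theoretical 2λ/τ.
    """
    p = p or cable.CableParameters()
    lam = lambda_um(diam_um, p.rm, p.ra)
    Ltot = length_lambda * lam
    m = builders.cylinder_cell(Ltot, diam_um, soma_diam=diam_um, spacing=25.0)
    stim = cable.StimulusSpec(kind="alpha", location=(2, 1.0), **DEFAULT_ALPHA)
    probes = [
        cable.Probe((2, (Ltot - pl * lam) / Ltot), label=f"{pl}lam")
        for pl in probe_lambdas
    ]
    duration = 6.0 * p.tau
    model = cable.build_model(m, p, policy)
    res = cable.simulate(model, [stim], probes, duration=duration, dt=dt, out_dt=0.01)
    t_near = res.peak_time(f"{probe_lambdas[0]}lam")
    t_far = res.peak_time(f"{probe_lambdas[1]}lam")
    delta_t = t_far - t_near
    if delta_t <= 0:
        raise cable.SolverError("peak order inverted; probes too close or record too short")
    v_lambda_tau = (probe_lambdas[1] - probe_lambdas[0]) / (delta_t / p.tau)
    return {
        "velocity_lambda_tau": v_lambda_tau,
        "velocity_m_per_s": v_lambda_tau * lam / p.tau * 1e-3,
        "lambda_um": lam,
        "tau_ms": p.tau,
        "n_compartments": model.n,
    }


# the five published basal-load configurations: (length µm, diameter µm)
BALL_AND_STICK_CONFIGS = [(400.0, 12.0), (500.0, 14.0), (600.0, 16.0),
                          (700.0, 18.0), (800.0, 20.0)]


def ball_and_stick_experiment(
    configs: list[tuple[float, float] | None] = None,
    apical_diam_um: float = 3.0,
    soma_diam_um: float = 20.0,
    p: cable.CableParameters | None = None,
    distances_um: np.ndarray | None = None,
    apical_length_lambda: float = 20.0,
    policy: cable.CompartmentPolicy | None = None,
    dt: float = 0.025,
    duration: float = 60.0,
) -> pd.DataFrame:
    """Latency/velocity vs apical input distance for a family of basal loads.

    Each config is a single basal equivalent cylinder (length, diameter)
    attached at the soma, or ``None`` for no basal cable; the apical cable is
    long (default 20 λ — effectively infinite at the probed range).  Larger
    basal cylinders impose a larger conductance load at the soma, which
    speeds up the apical EPSP peak on its way to the soma.
    """
    p = p or cable.CableParameters()
    configs = BALL_AND_STICK_CONFIGS if configs is None else configs
    if not configs:
        raise ValueError("configs must be non-empty")
    if distances_um is None:
        distances_um = np.arange(100.0, 801.0, 100.0)
    lam = lambda_um(apical_diam_um, p.rm, p.ra)
    ap_len = apical_length_lambda * lam
    policy = policy or cable.CompartmentPolicy(max_length_um=25.0)
    rows = []
    soma_probe_lbl = "soma"
    for cfg in configs:
        m = builders.ball_and_stick_cell(ap_len, apical_diam_um, soma_diam_um, basal=cfg)
        model = cable.build_model(m, p, policy)
        for dist in distances_um:
            site = (2, dist / ap_len)
            stim = cable.StimulusSpec(kind="alpha", location=site, **DEFAULT_ALPHA)
            res = cable.simulate(
                model, [stim],
                [cable.Probe(site, label="site"), cable.Probe((1, 0.5), label=soma_probe_lbl)],
                duration=duration, dt=dt, out_dt=0.01,
            )
            latency = res.peak_time(soma_probe_lbl) - res.peak_time("site")
            rows.append(
                dict(
                    basal_length_um=cfg[0] if cfg else 0.0,
                    basal_diam_um=cfg[1] if cfg else 0.0,
                    distance_um=float(dist),
                    latency_ms=float(latency),
                    velocity_m_per_s=float(dist / latency * 1e-3),
                )
            )
    return pd.DataFrame(rows)


def cell_summary(m: mo.Morphology, p: cable.CableParameters,
                 latmap: LatencyMap | None = None, **map_kwargs) -> dict:
    """Per-cell summary row: mean site diameter/distance/L in the window,
    τ, and window-averaged latency and velocity."""
    latmap = latmap or epsp_latency_map(m, p, **map_kwargs)
    t = latmap.valid()
    lo, hi = latmap.window
    sel = t[(t.path_um >= lo) & (t.path_um <= hi)]
    if sel.empty:
        raise ValueError("no valid sites inside the summary window")
    diams = [
        m.sections[int(r.section)].point_at(float(r.arc))[1] for r in sel.itertuples()
    ]
    return {
        "d_avg_um": float(np.mean(diams)),
        "l_avg_um": float(sel.path_um.mean()),
        "L_avg_lambda": float(sel.L_lambda.mean()),
        "tau_ms": p.tau,
        "latency_ms": latmap.window_mean("latency_ms"),
        "velocity_m_per_s": latmap.window_mean("velocity_m_per_s"),
    }
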