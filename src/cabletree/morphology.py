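"""Neuronal morphologies: SWC I/O, metrics, subtree surgery, equivalent cables.

A :class:`Morphology` is a rooted tree of unbranched :class:`Section` objects
(soma / axon / basal / apical) carrying 3D sample points with per-point
diameters, following SWC semantics.  On top of the data model this module
provides

* :func:`load_swc` / :func:`save_swc` — plain-text SWC round trip,
* :func:`morphometrics` — cohort-comparable summary metrics,
* :func:`swap_basal_tree` — "hybrid cell" construction (replace the basal
  tree of one cell with another cell's basal tree),
* :func:`electrotonic_path` — path distance and electrotonic distance
  L = Σ l_i/λ_i from the soma, with λ = sqrt(d·Rm/(4·Ra)),
* :func:`equivalent_cable` — Rall's variable-diameter equivalent cable
  d_eq(X) = (Σ_j d_j(X)^(3/2))^(2/3) for a dendritic subtree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .units import CM_PER_UM, UM_PER_CM, lambda_um

SOMA = "soma"
AXON = "axon"
BASAL = "basal"
APICAL = "apical"
DENDRITIC_TYPES = (BASAL, APICAL)

SWC_TYPE_CODES = {1: SOMA, 2: AXON, 3: BASAL, 4: APICAL}
SWC_CODE_OF_TYPE = {v: k for k, v in SWC_TYPE_CODES.items()}


class MorphologyError(ValueError):
    """Invalid morphology (broken tree, bad diameters, missing sections)."""


class SWCFormatError(ValueError):
    """Malformed SWC input; the message names the offending record."""


@dataclass
class Section:
    """Unbranched neurite stretch: ordered 3D samples with diameters (µm).

    ``points[0]`` is the attachment point on the parent (duplicated from the
    parent's geometry); for the soma section itself there is no parent.
    """

    id: int
    type: str
    points: np.ndarray  # (N, 3) µm
    diams: np.ndarray  # (N,) µm
    parent: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.diams = np.asarray(self.diams, dtype=float).ravel()
        if len(self.diams) != len(self.points):
            raise MorphologyError(
                f"section {self.id}: {len(self.points)} points but {len(self.diams)} diameters"
            )

    @property
    def npoints(self) -> int:
        return len(self.points)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def arc(self) -> np.ndarray:
        """Cumulative arc length at each sample point (µm)."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def area(self) -> float:
        """Lateral membrane area (µm²), each segment a cylinder frustum."""
        r = self.diams / 2.0
        l = self.segment_lengths
        slant = np.sqrt(l**2 + np.diff(r) ** 2)
        return float(np.sum(np.pi * (r[:-1] + r[1:]) * slant))

    @property
    def mean_diam(self) -> float:
        """Length-weighted mean diameter (µm); plain mean for zero length."""
        l = self.segment_lengths
        if l.sum() <= 0:
            return float(self.diams.mean())
        dmid = 0.5 * (self.diams[:-1] + self.diams[1:])
        return float(np.sum(dmid * l) / l.sum())

    def point_at(self, arc_pos: float) -> tuple[np.ndarray, float]:
        """Interpolated (position, diameter) at fractional arc ``arc_pos`` ∈ [0, 1]."""
        arc_pos = float(np.clip(arc_pos, 0.0, 1.0))
        a = self.arc
        s = arc_pos * a[-1]
        i = int(np.searchsorted(a, s, side="right") - 1)
        i = min(max(i, 0), self.npoints - 2) if self.npoints > 1 else 0
        if self.npoints == 1:
            return self.points[0].copy(), float(self.diams[0])
        seg = a[i + 1] - a[i]
        f = 0.0 if seg == 0 else (s - a[i]) / seg
        pos = self.points[i] * (1 - f) + self.points[i + 1] * f
        d = self.diams[i] * (1 - f) + self.diams[i + 1] * f
        return pos, float(d)


def soma_cylinder(center: np.ndarray, diam: float, sec_id: int = 1) -> Section:
    """Soma as a single cylinder of length = diameter, oriented along y."""
    c = np.asarray(center, dtype=float)
    half = np.array([0.0, diam / 2.0, 0.0])
    return Section(
        id=sec_id, type=SOMA, points=np.vstack([c - half, c + half]), diams=np.array([diam, diam])
    )


class Morphology:
    """Rooted tree of sections; the root is the (single) soma section."""

    def __init__(self, sections: Iterable[Section], metadata: dict | None = None):
        self.sections: dict[int, Section] = {}
        for sec in sections:
            if sec.id in self.sections:
                raise MorphologyError(f"duplicate section id {sec.id}")
            self.sections[sec.id] = sec
        roots = [s.id for s in self.sections.values() if s.parent is None]
        somas = [s.id for s in self.sections.values() if s.type == SOMA]
        if len(roots) != 1 or len(somas) != 1 or roots != somas:
            raise MorphologyError(
                f"expected exactly one root soma section, found roots={roots}, somas={somas}"
            )
        self.root: int = roots[0]
        self.metadata: dict = dict(metadata or {})
        self._children: dict[int, list[int]] = {i: [] for i in self.sections}
        for sec in self.sections.values():
            if sec.parent is not None:
                if sec.parent not in self.sections:
                    raise MorphologyError(
                        f"section {sec.id} references missing parent {sec.parent}"
                    )
                self._children[sec.parent].append(sec.id)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def soma(self) -> Section:
        return self.sections[self.root]

    @property
    def soma_center(self) -> np.ndarray:
        return self.soma.points.mean(axis=0)

    def children(self, sec_id: int) -> list[int]:
        return list(self._children[sec_id])

    def sections_of_type(self, *types: str) -> list[Section]:
        return [s for s in self.sections.values() if s.type in types]

    def path_to_root(self, sec_id: int) -> list[int]:
        """Section ids from ``sec_id`` up to (and including) the root."""
        out = [sec_id]
        while self.sections[out[-1]].parent is not None:
            out.append(self.sections[out[-1]].parent)
        return out

    def validate(self) -> None:
        """Raise :class:`MorphologyError` on any violated invariant."""
        g = nx.DiGraph()
        g.add_nodes_from(self.sections)
        for sec in self.sections.values():
            if sec.parent is not None:
                g.add_edge(sec.parent, sec.id)
        if not nx.is_arborescence(g):
            raise MorphologyError("section graph is not a rooted tree")
        for sec in self.sections.values():
            if sec.type not in SWC_CODE_OF_TYPE:
                raise MorphologyError(f"section {sec.id}: unknown type {sec.type!r}")
            if np.any(sec.diams <= 0):
                raise MorphologyError(f"section {sec.id}: non-positive diameter")
            if sec.type != SOMA and sec.npoints < 2:
                raise MorphologyError(f"section {sec.id}: non-soma section needs >= 2 points")
            if np.any(sec.segment_lengths < 0):  # pragma: no cover - norms are >= 0
                raise MorphologyError(f"section {sec.id}: negative segment length")

    def copy(self) -> "Morphology":
        secs = [
            Section(s.id, s.type, s.points.copy(), s.diams.copy(), s.parent)
            for s in self.sections.values()
        ]
        return Morphology(secs, metadata=dict(self.metadata))


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def load_swc(path, shrinkage: tuple[float, float] | None = None) -> Morphology:
    """Read an SWC file into a :class:`Morphology`.

    Parameters
    ----------
    path:
        SWC file (7 whitespace-separated columns: id, type, x, y, z, radius,
        parent; ``#`` comments allowed).
    shrinkage:
        Optional ``(xy, z)`` multiplicative correction for tissue shrinkage,
        applied to coordinates (x, y scaled by ``xy``; z by ``z``) and to
        diameters (by ``xy``) before any downstream use.

    The soma is collapsed to a single cylinder of length = diameter
    (diameter = twice the mean soma-sample radius), centred on the mean soma
    sample position.  Dendritic/axonal samples are grouped into unbranched
    sections deterministically (splitting at branch points and type changes).
    """
    nodes: dict[int, tuple[int, np.ndarray, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCFormatError(f"line {lineno}: expected 7 columns, got {len(cols)}: {raw!r}")
            try:
                nid, tcode = int(cols[0]), int(cols[1])
                xyz = np.array([float(cols[2]), float(cols[3]), float(cols[4])])
                radius, parent = float(cols[5]), int(cols[6])
            except ValueError as exc:
                raise SWCFormatError(f"line {lineno}: unparsable record {raw!r}") from exc
            if tcode not in SWC_TYPE_CODES:
                raise SWCFormatError(f"line {lineno}: unknown SWC type code {tcode} (record {nid})")
            if radius <= 0:
                raise SWCFormatError(f"line {lineno}: non-positive radius for record {nid}")
            if nid in nodes:
                raise SWCFormatError(f"line {lineno}: duplicate record id {nid}")
            nodes[nid] = (tcode, xyz, radius, parent)
            order.append(nid)
    if not nodes:
        raise SWCFormatError("empty SWC file")
    for nid in order:
        parent = nodes[nid][3]
        if parent != -1 and parent not in nodes:
            raise SWCFormatError(f"record {nid} references missing parent {parent}")

    if shrinkage is not None:
        sxy, sz = float(shrinkage[0]), float(shrinkage[1])
        scale = np.array([sxy, sxy, sz])
        nodes = {
            nid: (t, xyz * scale, r * sxy, par) for nid, (t, xyz, r, par) in nodes.items()
        }

    soma_ids = [nid for nid in order if nodes[nid][0] == 1]
    if not soma_ids:
        raise SWCFormatError("no soma (type 1) records in SWC file")
    soma_pts = np.array([nodes[n][1] for n in soma_ids])
    soma_diam = 2.0 * float(np.mean([nodes[n][2] for n in soma_ids]))
    soma_sec = soma_cylinder(soma_pts.mean(axis=0), soma_diam, sec_id=1)

    children: dict[int, list[int]] = {nid: [] for nid in order}
    for nid in order:
        par = nodes[nid][3]
        if par != -1:
            children[par].append(nid)

    # section starts: non-soma nodes whose parent is soma, absent (-1 is
    # rejected below for non-soma), a branch point, or of a different type
    sections: list[Section] = [soma_sec]
    next_id = 2
    soma_set = set(soma_ids)
    sec_of_node: dict[int, int] = {n: 1 for n in soma_ids}

    def is_start(nid: int) -> bool:
        tcode, _, _, par = nodes[nid]
        if tcode == 1:
            return False
        if par == -1:
            raise SWCFormatError(f"non-soma record {nid} has no parent")
        if par in soma_set:
            return True
        ptcode = nodes[par][0]
        return ptcode != tcode or len(children[par]) > 1

    starts = [nid for nid in order if is_start(nid)]
    for start in starts:
        tcode, _, _, par = nodes[start]
        chain = [start]
        while True:
            kids = children[chain[-1]]
            if len(kids) == 1 and nodes[kids[0]][0] == tcode:
                chain.append(kids[0])
            else:
                break
        # attachment point: parent node geometry (soma -> soma centre)
        if par in soma_set:
            p0 = soma_pts.mean(axis=0)
            d0 = 2.0 * nodes[start][2]
            parent_sec = 1
        else:
            p0 = nodes[par][1]
            d0 = 2.0 * nodes[par][2]
            parent_sec = sec_of_node[par]
        pts = np.vstack([p0] + [nodes[n][1] for n in chain])
        dia = np.array([d0] + [2.0 * nodes[n][2] for n in chain])
        sec = Section(next_id, SWC_TYPE_CODES[tcode], pts, dia, parent=parent_sec)
        for n in chain:
            sec_of_node[n] = next_id
        sections.append(sec)
        next_id += 1

    meta = {"source": str(path)}
    if shrinkage is not None:
        meta["shrinkage"] = (sxy, sz)
    return Morphology(sections, metadata=meta)


def save_swc(m: Morphology, path) -> None:
    """Write a :class:`Morphology` as SWC.

    The soma is written as a single record (radius = diameter/2 at the soma
    centre); each further section writes its samples 1..N (sample 0 is the
    attachment point owned by the parent), so load → save → load is identity
    on section counts, lengths and diameters.
    """
    lines = ["# SWC written by cabletree"]
    nid = 1
    c = m.soma_center
    soma_d = m.soma.mean_diam
    lines.append(f"1 1 {c[0]:.6f} {c[1]:.6f} {c[2]:.6f} {soma_d / 2.0:.6f} -1")
    last_node_of_sec: dict[int, int] = {m.root: 1}
    for sec in _preorder(m):
        if sec.id == m.root:
            continue
        parent_node = last_node_of_sec[sec.parent]
        for k in range(1, sec.npoints):
            nid += 1
            p, r = sec.points[k], sec.diams[k] / 2.0
            code = SWC_CODE_OF_TYPE[sec.type]
            lines.append(f"{nid} {code} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {r:.6f} {parent_node}")
            parent_node = nid
        last_node_of_sec[sec.id] = parent_node
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _preorder(m: Morphology) -> list[Section]:
    out, stack = [], [m.root]
    while stack:
        sid = stack.pop()
        out.append(m.sections[sid])
        stack.extend(sorted(m.children(sid), reverse=True))
    return out


def apply_diameter_fixes(m: Morphology, section_ids: Sequence[int]) -> Morphology:
    """Set each listed section's diameters to its parent's last diameter.

    Repair for sudden diameter jumps caused by unequal dye spread: the
    section's diameter profile is replaced by the constant value found at the
    distal end of its parent.
    """
    out = m.copy()
    for sid in section_ids:
        if sid not in out.sections:
            raise MorphologyError(f"diameter fix: no section {sid}")
        sec = out.sections[sid]
        if sec.parent is None:
            raise MorphologyError("diameter fix: cannot fix the soma section")
        d = out.sections[sec.parent].diams[-1]
        sec.diams = np.full_like(sec.diams, d)
    return out


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

@dataclass
class MorphometricsReport:
    """Summary metrics of a morphology (lengths/areas µm, µm²)."""

    total_length: float
    apical_length: float
    basal_length: float
    basal_area: float
    horizontal_extent: float
    vertical_extent: float
    trunk_diam_mean: float
    basal_radius_profile: pd.DataFrame = field(repr=False)
    no_dendrites: bool = False

    def as_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "apical_length": self.apical_length,
            "basal_length": self.basal_length,
            "basal_area": self.basal_area,
            "horizontal_extent": self.horizontal_extent,
            "vertical_extent": self.vertical_extent,
            "trunk_diam_mean": self.trunk_diam_mean,
        }


def _apical_trunk_sections(m: Morphology) -> list[Section]:
    """Heuristic apical trunk: from the apical root, repeatedly descend into
    the thickest child while its mean diameter stays >= 50% of the apical
    root section's mean diameter."""
    apical_roots = [
        s for s in m.sections_of_type(APICAL) if m.sections[s.parent].type == SOMA
    ]
    if not apical_roots:
        return []
    root = max(apical_roots, key=lambda s: s.mean_diam)
    ref = root.mean_diam
    trunk = [root]
    while True:
        kids = [m.sections[c] for c in m.children(trunk[-1].id) if m.sections[c].type == APICAL]
        if not kids:
            break
        nxt = max(kids, key=lambda s: s.mean_diam)
        if nxt.mean_diam < 0.5 * ref:
            break
        trunk.append(nxt)
    return trunk


def morphometrics(m: Morphology, profile_bin_um: float = 20.0) -> MorphometricsReport:
    """Compute cohort-comparable metrics.

    Lengths are sums of 3D segment lengths; membrane areas treat segments as
    cylinder-frustum lateral surfaces; extents are bounding-box widths of the
    dendritic sample points (horizontal: x, vertical: y — the apical axis is
    y by convention).  The basal-radius profile sums basal radii per
    ``profile_bin_um`` path-distance bin.
    """
    dend = m.sections_of_type(*DENDRITIC_TYPES)
    apical = [s for s in dend if s.type == APICAL]
    basal = [s for s in dend if s.type == BASAL]
    if not dend:
        empty = pd.DataFrame({"bin_start_um": [], "radius_sum_um": []})
        return MorphometricsReport(0, 0, 0, 0, 0, 0, 0, empty, no_dendrites=True)

    apical_len = sum(s.length for s in apical)
    basal_len = sum(s.length for s in basal)
    basal_area = sum(s.area for s in basal)
    pts = np.vstack([s.points for s in dend])
    hor = float(pts[:, 0].max() - pts[:, 0].min())
    ver = float(pts[:, 1].max() - pts[:, 1].min())

    trunk = _apical_trunk_sections(m)
    if trunk:
        tl = np.array([s.length for s in trunk])
        td = np.array([s.mean_diam for s in trunk])
        trunk_diam = float(np.sum(td * tl) / tl.sum()) if tl.sum() > 0 else float(td.mean())
    else:
        trunk_diam = 0.0

    # basal radius profile: per path-distance bin, sum over branches of each
    # branch's (length-weighted mean) radius in that bin
    dist_cache = _section_start_distances(m)
    rows: dict[int, float] = {}
    for s in basal:
        arc = s.arc
        per_bin: dict[int, tuple[float, float]] = {}
        for i in range(s.npoints - 1):
            lo_d, hi_d = dist_cache[s.id] + arc[i], dist_cache[s.id] + arc[i + 1]
            if hi_d <= lo_d:
                continue
            rmid = 0.25 * (s.diams[i] + s.diams[i + 1])
            for b in range(int(lo_d // profile_bin_um), int(hi_d // profile_bin_um) + 1):
                o0, o1 = max(lo_d, b * profile_bin_um), min(hi_d, (b + 1) * profile_bin_um)
                w = o1 - o0
                if w <= 1e-12:
                    continue
                sw, ww = per_bin.get(b, (0.0, 0.0))
                per_bin[b] = (sw + rmid * w, ww + w)
        for b, (sw, ww) in per_bin.items():
            rows[b] = rows.get(b, 0.0) + sw / ww
    profile = pd.DataFrame(
        {
            "bin_start_um": [b * profile_bin_um for b in sorted(rows)],
            "radius_sum_um": [rows[b] for b in sorted(rows)],
        }
    )
    return MorphometricsReport(
        total_length=apical_len + basal_len,
        apical_length=apical_len,
        basal_length=basal_len,
        basal_area=basal_area,
        horizontal_extent=hor,
        vertical_extent=ver,
        trunk_diam_mean=trunk_diam,
        basal_radius_profile=profile,
    )


def _section_start_distances(m: Morphology) -> dict[int, float]:
    """3D path distance from the soma to the start (point 0) of each section."""
    out = {m.root: 0.0}
    for sec in _preorder(m):
        if sec.id == m.root:
            continue
        if sec.parent == m.root:
            out[sec.id] = 0.0
        else:
            out[sec.id] = out[sec.parent] + m.sections[sec.parent].length
    return out


# ---------------------------------------------------------------------------
# Hybrid cells
# ---------------------------------------------------------------------------

def swap_basal_tree(recipient: Morphology, donor: Morphology) -> Morphology:
    """Replace the recipient's basal tree by the donor's ("hybrid cell").

    All basal sections of ``recipient`` are removed; all basal sections of
    ``donor`` are translated so the donor soma centre maps onto the recipient
    soma centre (donor-internal geometry preserved) and re-rooted onto the
    recipient soma.  Soma, axon and apical tree of the recipient keep their
    ids and geometry, so site keys on the apical tree remain comparable
    between original and hybrid.
    """
    donor_basal = donor.sections_of_type(BASAL)
    if not donor_basal:
        raise MorphologyError("donor morphology has no basal sections")
    keep = [
        Section(s.id, s.type, s.points.copy(), s.diams.copy(), s.parent)
        for s in recipient.sections.values()
        if s.type != BASAL
    ]
    kept_ids = {s.id for s in keep}
    for s in keep:
        if s.parent is not None and s.parent not in kept_ids:
            raise MorphologyError(
                f"non-basal section {s.id} hangs off a basal section; cannot swap"
            )
    shift = recipient.soma_center - donor.soma_center
    next_id = max(kept_ids) + 1
    idmap: dict[int, int] = {}
    new_secs: list[Section] = []
    for s in sorted(donor_basal, key=lambda s: len(donor.path_to_root(s.id))):
        parent = donor.sections[s.parent]
        if parent.type == SOMA:
            new_parent = recipient.root
        elif parent.type == BASAL:
            new_parent = idmap[parent.id]
        else:
            raise MorphologyError(f"donor basal section {s.id} attached to {parent.type}")
        pts = s.points + shift
        if parent.type == SOMA:
            pts = pts.copy()
            pts[0] = recipient.soma_center
        idmap[s.id] = next_id
        new_secs.append(Section(next_id, BASAL, pts, s.diams.copy(), new_parent))
        next_id += 1
    meta = dict(recipient.metadata)
    meta["basal_donor"] = donor.metadata.get("label", "donor")
    return Morphology(keep + new_secs, metadata=meta)


# ---------------------------------------------------------------------------
# Electrotonic geometry
# ---------------------------------------------------------------------------

def electrotonic_path(m: Morphology, loc: tuple[int, float], p) -> tuple[float, float]:
    """Path distance (µm) and electrotonic distance L (λ units) from the soma.

    ``loc`` is ``(section_id, arc)`` with arc ∈ [0, 1] along the section.
    L sums l_i/λ_i over segments on the soma-to-site path, with the segment
    space constant λ_i = sqrt(d_i·Rm/(4·Ra)) evaluated at the segment's mean
    diameter.  A location on the soma returns (0, 0).
    """
    sid, arc_pos = loc
    if sid not in m.sections:
        raise MorphologyError(f"no section {sid}")
    if m.sections[sid].type == SOMA:
        return 0.0, 0.0
    chain = m.path_to_root(sid)[::-1]  # root .. target
    dist = 0.0
    L = 0.0
    for k, cid in enumerate(chain):
        sec = m.sections[cid]
        if sec.type == SOMA:
            continue
        if cid == sid:
            stop = float(np.clip(arc_pos, 0.0, 1.0)) * sec.length
        else:
            stop = sec.length
        run = 0.0
        arcs = sec.arc
        for i in range(sec.npoints - 1):
            l = arcs[i + 1] - arcs[i]
            if l <= 0:
                continue
            take = min(l, max(0.0, stop - run))
            if take <= 0:
                break
            dmid = 0.5 * (sec.diams[i] + sec.diams[i + 1])
            L += take / lambda_um(dmid, p.rm, p.ra)
            dist += take
            run += l
    return dist, L


@dataclass
class EquivalentCable:
    """Rall equivalent cable of a subtree: d_eq per electrotonic-distance bin."""

    X: np.ndarray  # bin centres, λ units
    d_eq: np.ndarray  # µm
    subtree: str
    dX: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"X_lambda": self.X, "d_eq_um": self.d_eq})


def equivalent_cable(m: Morphology, subtree: str, p, dX: float = 0.01) -> EquivalentCable:
    """Equivalent-cable diameter profile d_eq(X) = (Σ_j d_j(X)^{3/2})^{2/3}.

    X is electrotonic distance from the soma (per-segment λ summation as in
    :func:`electrotonic_path`); the sum runs over all branches alive at X.
    A branch contributes to a bin if its electrotonic span overlaps the bin;
    within one branch and bin the length-weighted mean diameter is used.
    """
    if subtree not in DENDRITIC_TYPES:
        raise ValueError(f"subtree must be one of {DENDRITIC_TYPES}, got {subtree!r}")
    secs = m.sections_of_type(subtree)
    if not secs:
        raise MorphologyError(f"morphology has no {subtree} sections")
    # electrotonic distance to section starts
    Xstart: dict[int, float] = {}
    for sec in _preorder(m):
        if sec.type != subtree:
            continue
        parent = m.sections[sec.parent]
        if parent.type == subtree:
            base = Xstart[sec.parent] + _section_eL(parent, p)
        else:
            base = 0.0
        Xstart[sec.id] = base

    # accumulate per-branch, per-bin mean diameter, then the 3/2-power sum
    acc: dict[int, float] = {}
    for sec in secs:
        X0 = Xstart[sec.id]
        per_bin: dict[int, tuple[float, float]] = {}  # bin -> (Σ d·w, Σ w)
        x = X0
        for i in range(sec.npoints - 1):
            l = float(np.linalg.norm(sec.points[i + 1] - sec.points[i]))
            if l <= 0:
                continue
            dmid = 0.5 * (sec.diams[i] + sec.diams[i + 1])
            dXseg = l / lambda_um(dmid, p.rm, p.ra)
            b0, b1 = int(x // dX), int((x + dXseg) // dX)
            for b in range(b0, b1 + 1):
                lo, hi = max(x, b * dX), min(x + dXseg, (b + 1) * dX)
                w = hi - lo
                if w <= 1e-12 * dX:  # zero-measure overlap at a bin boundary
                    continue
                sw, ww = per_bin.get(b, (0.0, 0.0))
                per_bin[b] = (sw + dmid * w, ww + w)
            x += dXseg
        for b, (sw, ww) in per_bin.items():
            acc[b] = acc.get(b, 0.0) + (sw / ww) ** 1.5
    nbins = max(acc) + 1
    d_eq = np.zeros(nbins)
    for b, v in acc.items():
        d_eq[b] = v ** (2.0 / 3.0)
    X = (np.arange(nbins) + 0.5) * dX
    return EquivalentCable(X=X, d_eq=d_eq, subtree=subtree, dX=dX)


def _section_eL(sec: Section, p) -> float:
    """Electrotonic length of a full section."""
    L = 0.0
    for i in range(sec.npoints - 1):
        l = float(np.linalg.norm(sec.points[i + 1] - sec.points[i]))
        if l <= 0:
            continue
        dmid = 0.5 * (sec.diams[i] + sec.diams[i + 1])
        L += l / lambda_um(dmid, p.rm, p.ra)
    return L
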