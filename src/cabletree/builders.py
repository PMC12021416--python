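"""Programmatic construction of simple stylised morphologies.

These builders produce valid :class:`~cabletree.morphology.Morphology`
objects for controlled experiments: single uniform/tapered cylinders and
ball-and-stick cells (soma + long apical cylinder + one equivalent basal
cylinder).  Geometry is laid out in the x–y plane with the apical axis +y.
"""

from __future__ import annotations

import numpy as np

from .morphology import APICAL, BASAL, Morphology, Section, soma_cylinder


def _line_section(
    sec_id: int,
    parent: int,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    diam_start: float,
    diam_end: float | None = None,
    sec_type: str = APICAL,
    spacing: float = 10.0,
) -> Section:
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n = max(1, int(np.ceil(length / spacing)))
    s = np.linspace(0.0, length, n + 1)
    pts = np.asarray(start)[None, :] + s[:, None] * direction[None, :]
    de = diam_start if diam_end is None else diam_end
    diams = np.linspace(diam_start, de, n + 1)
    return Section(sec_id, sec_type, pts, diams, parent=parent)


def cylinder_cell(
    length_um: float,
    diam_um: float,
    soma_diam: float | None = None,
    sec_type: str = APICAL,
    taper_to: float | None = None,
    spacing: float = 10.0,
) -> Morphology:
    """Soma + one unbranched cylinder (optionally tapered) along +y.

    With ``soma_diam`` equal to the cable diameter the soma is a short
    continuation of the cable; with a tiny ``soma_diam`` it approximates a
    sealed end.
    """
    sd = diam_um if soma_diam is None else soma_diam
    soma = soma_cylinder(np.zeros(3), sd, sec_id=1)
    cable = _line_section(
        2, 1, np.zeros(3), [0.0, 1.0, 0.0], length_um, diam_um,
        taper_to, sec_type=sec_type, spacing=spacing,
    )
    return Morphology([soma, cable], metadata={"label": f"cylinder_{length_um:g}x{diam_um:g}"})


def ball_and_stick_cell(
    apical_length_um: float,
    apical_diam_um: float = 3.0,
    soma_diam_um: float = 20.0,
    basal: tuple[float, float] | None = None,
    spacing: float = 10.0,
) -> Morphology:
    """Soma + apical cylinder (+y) + optional single basal cylinder (−y).

    ``basal`` is (length µm, diameter µm): the equivalent-cylinder stand-in
    for a whole basal tree acting as a conductance load at the soma.
    """
    soma = soma_cylinder(np.zeros(3), soma_diam_um, sec_id=1)
    secs = [
        soma,
        _line_section(2, 1, np.zeros(3), [0, 1.0, 0], apical_length_um,
                      apical_diam_um, sec_type=APICAL, spacing=spacing),
    ]
    if basal is not None:
        bl, bd = basal
        if bl <= 0 or bd <= 0:
            raise ValueError("basal (length, diameter) must be positive")
        secs.append(
            _line_section(3, 1, np.zeros(3), [0, -1.0, 0], bl, bd,
                          sec_type=BASAL, spacing=spacing)
        )
    label = f"ball_and_stick_ap{apical_length_um:g}" + (
        f"_ba{basal[0]:g}x{basal[1]:g}" if basal else "_nobasal"
    )
    return Morphology(secs, metadata={"label": label})
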