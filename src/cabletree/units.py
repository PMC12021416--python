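"""Unit conventions and conversions.

External interfaces use the units of the experimental literature:

* geometry: micrometres (µm)
* specific membrane capacitance Cm: µF/cm²
* specific membrane resistivity Rm: Ω·cm²
* specific axial resistivity Ra: Ω·cm
* time: milliseconds; voltage: millivolts; current: nanoamperes

Internally the simulator works in a consistent (mV, ms, nA, µS, nF, MΩ)
system, in which ``C[nF]·dV/dt[mV/ms] = I[nA]`` and ``g[µS]·V[mV] = I[nA]``
hold without extra factors.  Cable-theoretic quantities (λ, axial
resistances) are evaluated with lengths in cm, the native unit of the
specific constants, and converted at the boundary.
"""

UM_PER_CM = 1.0e4
CM_PER_UM = 1.0e-4

# area: 1 µm² = 1e-8 cm²
CM2_PER_UM2 = 1.0e-8


def lambda_um(diam_um: float, rm: float, ra: float) -> float:
    """Space constant λ (µm) of a cable of diameter ``diam_um`` (µm).

    λ = sqrt(d·Rm / (4·Ra)) with d in cm, Rm in Ω·cm², Ra in Ω·cm.
    """
    import numpy as np

    d_cm = diam_um * CM_PER_UM
    return float(np.sqrt(d_cm * rm / (4.0 * ra))) * UM_PER_CM


def tau_ms(cm: float, rm: float) -> float:
    """Membrane time constant τ = Rm·Cm, in ms when Rm in Ω·cm², Cm in µF/cm²."""
    return rm * cm * 1.0e-3
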