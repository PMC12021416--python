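"""Recover passive membrane constants from dual-electrode step responses.

A two-cylinder cell (soma + 500 µm dendrite) is simulated with the published
Human5 parameter set (Cm = 0.63 µF/cm², Rm = 15,570 Ωcm², Ra = 109 Ωcm,
spine factor 1.9 beyond 60 µm).  −100 pA, 300 ms steps are injected at the
soma and at the dendritic electrode in turn, recording both sites each time.
The fit starts from values perturbed ±50% and should return to the truth.
"""

import numpy as np

import cabletree as ct

truth = ct.fitted_cable_parameters("Human5")
cell = ct.ball_and_stick_cell(500.0, 2.0, soma_diam_um=20.0)
electrodes = ((1, 0.5), (2, 0.6))  # soma, dendrite at 300 µm

recording, _ = ct.generate_dual_electrode_recording(
    cell, truth, electrodes, noise_sigma_mV=0.0,
    amplitude_nA=-0.1, step_duration_ms=300.0)

rng = np.random.default_rng(2024)
signs = rng.choice([-0.5, 0.5], 3)
init = truth.with_values(cm=truth.cm * (1 + signs[0]),
                         rm=truth.rm * (1 + signs[1]),
                         ra=truth.ra * (1 + signs[2]))
print(f"truth : Cm={truth.cm:.3f} µF/cm²  Rm={truth.rm:.0f} Ωcm²  Ra={truth.ra:.0f} Ωcm")
print(f"start : Cm={init.cm:.3f}          Rm={init.rm:.0f}        Ra={init.ra:.0f}")

fit = ct.fit_passive_params(cell, recording, init, seed=7)
print(f"fitted: Cm={fit.cm:.3f} µF/cm²  Rm={fit.rm:.0f} Ωcm²  Ra={fit.ra:.0f} Ωcm")
print(f"        τ = Rm·Cm = {fit.tau_ms:.2f} ms")
print(f"        residual RMS per trace: "
      + ", ".join(f"{r:.2e}" for r in fit.residual_rms_mV) + " mV")
print(f"        converged={fit.converged}, {fit.n_evaluations} objective evaluations")
print("\nWith noiseless synthetic data the three constants are recovered to")
print("numerical precision; cross-location traces are what pin down Ra.")
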