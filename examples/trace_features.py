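"""Feature extraction from (synthetic) electrophysiological recordings.

Runs each of the bespoke trace algorithms on generated data with a known
ground truth: EPSP onset (two-line method), bAP latency/speed, AIS-corrected
axonal velocity, nucleated-patch capacitance and EM membrane thickness.
"""

import numpy as np

import cabletree as ct

# --- synaptic latency: two-line EPSP onset detection -----------------------
pre, post, truth = ct.generate_paired_epsp_traces(latency_ms=1.1,
                                                  amplitude_mV=1.0, seed=3)
lat = ct.synaptic_latency(post, pre.ap_peaks[0])
print(f"synaptic latency  : {lat:.3f} ms  (generated: 1.100 ms)")

# --- bAP latency and speed --------------------------------------------------
t = np.arange(400) / 20.0  # 20 kHz so the 0.5 ms shift lies on the grid
ap = lambda t0: ct.Trace(-70 + 110 * np.exp(-((t - t0) ** 2) / (2 * 0.15**2)),
                         20000.0)
latency, speed = ct.bap_latency_and_speed(ap(5.0), ap(5.5), distance_um=150.0)
print(f"bAP latency/speed : {latency:.3f} ms, {speed:.3f} m/s "
      f"(150 µm shifted by 0.5 ms → 0.3 m/s)")

# --- axonal AP velocity with AIS correction ---------------------------------
meas = ct.AxonBlebMeasurement(l_um=268.203, t_ms=0.333, ais_um=35.0)
print(f"axonal velocity   : {ct.correct_axonal_velocity(meas):.3f} m/s "
      f"(AP starts at the AIS, covers l − 2·ais)")
print(f"   literal reading: {ct.correct_axonal_velocity(meas, literal=True):.3f} m/s")

# --- nucleated-patch specific capacitance -----------------------------------
rate = 1.0e6
tt = np.arange(0, 2.0, 1000.0 / rate)
i_pA = 5.0 / 10.0 * np.exp(-tt / 0.01) * 1000.0  # 1 pF through 10 MΩ, 5 mV step
patch = ct.NucleatedPatchMeasurement(10.0, 10.0, [i_pA], [np.zeros_like(i_pA)],
                                     rate=rate)
out = ct.nucleated_patch_cm(patch, delta_v_mV=5.0)
print(f"patch capacitance : C = {out['c_pF']:.3f} pF on A = {out['area_um2']:.1f} µm² "
      f"→ Cm = {out['cm_uF_per_cm2']:.3f} µF/cm²")

# --- EM membrane thickness ---------------------------------------------------
profile, _ = ct.generate_em_profile(thickness_nm=4.271, seed=3)
print(f"membrane thickness: {ct.membrane_thickness(profile):.2f} nm "
      f"(generated: 4.271 nm, gradient threshold 50)")
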