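# Methods

This note documents the models, numerical choices and synthetic-data design
behind `cabletree`, and what the test suite does and does not establish.

## Passive cable model

Every neurite is a one-dimensional core conductor.  A morphology is a rooted
tree of unbranched sections carrying 3D sample points with per-point
diameters (SWC semantics: type codes 1 = soma, 2 = axon, 3 = basal,
4 = apical; unknown codes are rejected).  The soma is collapsed to a single
cylinder of length = diameter (diameter: twice the mean soma-sample radius).
The multi-point soma contours found in some reconstructions carry shape
information this representation discards; only total somatic area matters to
a passive model, and the cylinder preserves it to first order.

Membrane and axial properties derive from three specific constants with the
units used throughout experimental cable work: C_m (µF/cm²), R_m (Ω·cm²),
R_a (Ω·cm).  Derived scales: λ = sqrt(d·R_m/(4·R_a)) per segment of
diameter d, τ = R_m·C_m.  All geometry is µm externally; conversions to cm
happen in one module (`units`).

**Spine correction.**  Dendritic spines are not represented geometrically.
Dendritic membrane at a path distance ≥ `spine_onset` (default 60 µm) from
the soma is corrected by a scalar factor F — C_m·F and R_m/F — i.e. the
spine membrane is smeared into the shaft.  F defaults to 1 and is set to
1.9 (human) or 1.5 (rat) in species-level work.  The correction applies in
`build_model` and therefore identically inside the parameter fit.

**Discretisation.**  Each section is split into compartments no longer than
min(0.05·λ_section, `max_length_um`) (default 5 µm; coarser values are used
deliberately in long-cable experiments and are stated per run).  Compartment
membrane area is the frustum lateral surface integrated over the tapered
sample geometry; axial resistances use the exact 4·R_a·l/(π·d₀·d₁) form for
a linearly tapered piece, split at the compartment midpoint.  Ends are
sealed.  Zero-length sections collapse onto their parent node.

**Integration.**  Crank–Nicolson (second order, unconditionally stable),
default dt = 0.005 ms, with the system matrix LU-factorised once per
simulation.  Outputs are resampled to the 0.01 ms analysis bin on which all
peak times are read; peak time is the first sample attaining the maximum.
Voltages are deflections from rest (a passive system has no preferred
resting level), so an unstimulated model stays at exactly zero.
Convergence: halving dt and compartment length moves reported latencies by
less than one 0.01 ms bin (tested).

**Recording electrode.**  A probe may carry a series resistance R_s (MΩ)
to an ideal amplifier with a residual pipette capacitance (default 0.5 pF,
a capacitance-neutralised patch pipette).  The electrode never passes
steady current, so plateaus are unaffected; fast transients are low-passed
with time constant R_s·C_pip.  For R_s in the 40–200 MΩ range of thin
dendritic pipettes the latency maps inside the 27–289 µm analysis window
shift by a few percent at most (tested); isolated sub-10 µm sites with
~0.03 ms latencies can shift by more in relative terms, which is a
quantisation- and definition-dominated regime rather than a physical one.

## Latency and velocity maps

An alpha current I(t) = A(e^{−t/τ₁} − e^{−t/τ₀}) (A = 1.5 nA, τ₀ = 0.25 ms,
τ₁ = 1 ms; peak at 0.462 ms) is injected at each dendritic site in turn.
Latency = somatic peak time − local peak time; velocity = path distance /
latency.  Normalised columns use L = Σ l_i/λ_i (electrotonic distance) and
τ.  The summary curve averages sites per branch on a 1 µm distance grid,
then averages branches with equal weight, then smooths with a 10 µm rolling
window; the scalar "window mean" averages that curve over 27–289 µm, the
span of the dendritic recordings being emulated.  Equal branch weighting at
a shared distance is a choice; compartment-count weighting would bias the
average towards heavily subdivided branches.

Flat responses (no resolvable peak, or a somatic peak still rising at the
end of the record) are flagged and excluded from summaries.

## Equivalent cables and hybrid cells

The Rall equivalent cable of a subtree is d_eq(X) = (Σ_j d_j(X)^{3/2})^{2/3}
over branches j alive at electrotonic distance X, binned at dX = 0.01 λ; a
branch contributes to every bin its span overlaps, entering with its
length-weighted mean diameter in that bin.  At a branch point the parent
and daughters share one bin, so a perfectly Rall-matched junction shows a
single-bin excursion above the otherwise flat profile — an artifact of the
overlap rule, not of the geometry.

`swap_basal_tree` removes the recipient's basal sections and re-roots the
donor's basal sections at the recipient soma centre, preserving donor
geometry and all non-basal section ids, so latency maps of original and
hybrid cells are keyed to identical apical sites and subtract cleanly into
a latency-gram.

## The conductance-load experiment

The ball-and-stick family attaches a single sealed basal cylinder
(length 400–800 µm, diameter 12–20 µm in five steps) plus a 20 µm soma to a
long (20 λ, effectively infinite) 3 µm apical cable.  Two findings from
validating this experiment against an exact frequency-domain solution of
the continuous cable (an independent oracle, agreeing with the
compartmental solver to < 0.1 ms):

* With plain membrane (F = 1), the five-config latency family is *humped*:
  going from the smallest to the largest cylinder first raises, then lowers
  the apical-to-soma latency, and a cell with no basal cylinder at all is
  the fastest configuration.  A short fat cylinder is as much a capacitive
  load (which delays the somatic peak) as a resistive sink (which advances
  it), and the net sign depends on the mix.
* With spine-corrected membrane (F = 1.9 beyond 60 µm — the package's
  standard treatment of dendritic membrane, which raises the cylinder's
  conductance per area), the resistive-sink character dominates and the
  family is cleanly monotone at 100–300 µm input distances: larger basal
  loads give shorter latency and higher velocity.

The property test therefore exercises the five-config family under the
spine-corrected configuration, which is also the configuration under which
the hybrid-cell experiments on full branchy trees show the same sign
(there the effect is robust with or without F: a bigger basal tree speeds
apical EPSPs).  Far from the soma, every configuration's velocity converges
to the apical cable's 2λ/τ.

## Passive-parameter fitting

(C_m, R_m, R_a) are fitted by minimising the summed squared difference
between recorded and simulated voltages across all traces — by design the
cross-location pairs (dendritic step, somatic response, and vice versa) that
a dual-electrode protocol provides, which avoid the bridge-balance problem
and constrain R_a.  Repetitions are averaged and a pre-stimulus baseline is
subtracted first.  The optimiser is bounded Powell (conjugate directions,
derivative-free) on scaled parameters, bounds C_m ∈ [0.3, 2] µF/cm²,
R_m ∈ [3,000, 40,000] Ω·cm², R_a ∈ [50, 400] Ω·cm, with optional seeded
multi-start; the returned objective never exceeds the starting objective.
Forward simulations during fitting use dt = 0.1 ms and ≤10 µm compartments
— step responses are slow relative to both — and model traces are
interpolated onto the recording's 15 kHz time base.

Identifiability diagnostic: after the fit, each parameter is perturbed
±20%; if the objective moves by less than 1% (relative to the residual,
floored at 1% of the data's signal power so a perfect noiseless fit still
normalises), the parameter is reported as weakly constrained.  A somatic
electrode alone on a compact cell flags R_a; dual-electrode data does not.

Hyperpolarisation-activated (h-type) conductances are deliberately not
modelled; fits are meant for hyperpolarising steps where that nonlinearity
is smallest.

## Trace-feature algorithms

* **EPSP onset (two-line method).**  Line 1: least squares on the 1 ms
  baseline centred on the presynaptic AP peak.  Line 2: least squares on
  the samples between 5% and 30% of the EPSP amplitude (measured from the
  baseline line to the peak), located by walking back from the peak through
  the 30% and 5% crossings.  Onset = intersection of the two lines;
  synaptic latency = onset − AP peak.  Peak and amplitude are read from a
  0.2 ms box-smoothed deflection so single noisy samples cannot set the
  band; the fits themselves use raw samples.  Per-sweep scatter at
  realistic noise (σ ≈ 0.05 mV) is ~0.15 ms; the per-cell statistic is the
  mean delay over sweeps, which lands within 0.1 ms.
* **bAP latency/speed.**  First-AP sweeps are averaged; latency is the
  dendritic minus somatic peak time, speed = distance/latency.
* **Axonal velocity, AIS-corrected.**  Default physical reading: the AP
  starts at the axon initial segment (35 µm from the hillock) and travels
  both ways at one speed, so the soma→bleb delay covers l − 2·ais and
  v = (l − 2·ais)/t.  An alternative algebraic reading
  v = l/(t·(1 + ais/l)) is available behind a flag; both reduce to l/t at
  ais = 0.  Neither reading is validated against cohort means, because a
  mean of ratios is not the ratio of means.
* **Nucleated-patch C_m.**  Patch surface A = π·((a+b)/2)² from the two
  nucleus diameters; capacitance = charge of the residual-subtracted
  transient / voltage step (Q/ΔV), cross-checked against a
  single-exponential fit of the decay (A·τ recovers the same charge).
  Q/ΔV was chosen over τ/R_s because it needs no series-resistance
  estimate.
* **EM membrane thickness.**  Central-difference gradient magnitude of the
  intensity line profile (intensity units per sample); thickness = distance
  between the first and last samples exceeding the threshold (default 50).

All estimators are shift-equivariant, and the onset detector is
amplitude-scale invariant (the 5–30% band is relative).

## Synthetic-data generators

Every generator is a pure function of (parameters, seed) and returns a
ground-truth record alongside the data.

**Morphologies.**  Per-cell targets (apical length, basal length = total −
apical, horizontal/vertical extents, mean trunk diameter, basal membrane
area) are drawn from normal marginals matching the human/rat cohort
statistics.  A latent per-cell size factor (correlation 0.8 to every
target) keeps the marginals intact while making big cells big in
everything; without it, independent draws of basal length and basal area
imply unrealistic basal diameters and the area calibration degrades.  The
geometry realises the draws: a tapering trunk (1.3→0.7 × the target mean
diameter) along +y with obliques and a tuft above, 4–7 basal stems around
the soma, all grown in ~10 µm steps inside the extent box with "frame"
branches pinning the box edges so extents are met exactly; basal diameters
are rescaled post hoc so the basal area is met exactly.  Branch-length and
angle distributions are artifact-defined — the cohort statistics being
matched are means/SDs, not branching topology — so passing calibration
tests says nothing about higher-order structure of real dendritic trees
(tortuosity, branch-order statistics, 3D embedding).

**Recordings.**  Dual-electrode step protocols are simulated with the cable
model (−100 pA, 300 ms by default), sampled at 15 kHz, with i.i.d. Gaussian
noise added to the voltages.  Real recordings have coloured noise, drift
and electrode artifacts; recovery tests on this data therefore demonstrate
correctness of the estimation machinery, not robustness to every
experimental nuisance.

**Paired AP/EPSP traces.**  A narrow AP waveform plus a
difference-of-exponentials EPSP (τ_rise = 2 ms, τ_decay = 20 ms) whose
onset lags the AP peak by exactly the requested latency.

**EM profiles.**  Two opposing one-sample edges separated by the requested
thickness, with the half-contrast value at the edge-centre samples so the
central-difference gradient peaks exactly there; a contrast too low for the
threshold sets a warning flag.

## Problem sizes used in tests and the acceptance script

Synthetic cells are mapped with 20 µm compartments and site strides of
8–30; the long-cable asymptote uses a 10 λ cable (1734 compartments,
dt = 0.01 ms); fits use a soma + 500 µm dendrite cell at 15 kHz.  These
sizes resolve every quantity tested (convergence checks above) while
keeping the full suite and the acceptance script in the minutes range on
one CPU.

## Known limitations

* Purely passive: no Na⁺/K⁺/Ca²⁺/HCN conductances, no synaptic conductance
  change (current injection only), no temperature dependence.
* Uniform specific constants per cell; no per-branch gradients.
* The soma is a single isopotential cylinder; axial resistance within the
  soma is approximated by its half-cylinder value.
* Latency-map site keys survive hybrid-cell surgery but not an SWC
  round trip (the writer merges single-child section chains).
* The equivalent-cable profile carries a one-bin artifact at branch points
  (overlap binning, above).
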