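# Methods

`cardiomef` is a multiscale simulator of mechano-electric feedback (MEF) in
a contracting left ventricle.  Four coupled components form the model:
cellular electrophysiology, stretch-activated channel (SAC) current,
myofilament force development, and a fiber-based ventricular geometry with
monodomain propagation and lumped hemodynamics.  This note documents the
model equations, the numerical choices, every calibrated constant, and the
known limitations.

## Cellular electrophysiology

The myocyte is the 2004 ten Tusscher–Noble–Noble–Panfilov (TNNP) human
ventricular model with the mid-myocardial (M-cell) parameter set: 12
sarcolemmal currents, Na⁺/K⁺/Ca²⁺ concentration dynamics, SR uptake /
leak / Ca-induced-Ca-release, and algebraic (instantaneous) cytosolic and
SR Ca buffering solved by the standard quadratic update.  The membrane
equation is

    dVm/dt = −(Iion − Istim),
    Iion = INa + INaK + IbNa + IK1 + Ito + IKr + IKs + IpK
         + ICaL + INaCa + IpCa + IbCa + ISAC,

with all currents in pA/pF so the capacitance never rescales the equation
(a 52 pA/pF stimulus over 0.02 ms moves Vm by exactly +1.04 mV).  ISAC is a
lumped non-selective current: it depolarizes the membrane but is excluded
from the ionic concentration bookkeeping.

Two intentional departures from the plainest reading of the source
formulation:

* **Gate integration.**  Vm and the concentrations advance by forward Euler
  at Δt = 0.02 ms, but the 12 Hodgkin–Huxley gates use Rush–Larsen
  exponential updates.  The Na⁺ activation gate has τ_m ≈ 1 µs near rest,
  so plain forward Euler diverges at any practical step; the exponential
  update is exact for the locally linearized gate equation and is the
  canonical way this model is stepped at Δt = 0.02 ms.
* **fCa cap.**  The raw steady-state expression for the Ca-dependent ICaL
  gate reaches 1.048 at diastolic Ca; it is capped at 1.0 to keep all gates
  in [0, 1].  The cap is only active where ICaL is negligible.

Validation: the quiescent resting point converges to −86.4 mV with
|Iion| < 10⁻⁵ pA/pF, and the first stimulated beat gives an APD90 of
~337 ms — the published M-cell value class.

## Stretch-activated channel

The SAC is ohmic in voltage and sigmoidal in the stretch ratio
λ = HalfSL/HalfSL0 (HalfSL0 = 0.97 µm):

    I_SAC = G_SAC (Vm − V_rev) / (1 + K e^(−α(λ−1)))

with G_SAC = 0.025 nS/pF, V_rev = −20 mV, K = 1, α = 3 (the reference
parameter set).  `compute_isac` implements this law verbatim — at λ = 1 the
effective conductance is exactly G_SAC/2, the current is linear in
(Vm − V_rev), strictly increasing in λ, and saturates at G_SAC.

**Recruitment convention.**  The *drivers* (cell and tissue integrators,
protocols) recruit the channel only under stretch beyond rest length:
I_SAC(λ ≤ 1) = 0, I_SAC(λ > 1) = the law above (`recruited_isac`).  This is
a deliberate design decision: the unstretched control then coincides with
the original myocyte model, and in the contracting ventricle a fiber whose
systolic shortening takes it below rest length silences its SAC.  It is the
only convention under which the control preload series is insensitive to
preload (shortening puts λ(t) below 1 through repolarization for moderate
preloads) while sustained large preloads and weakly contracting (failing)
ventricles keep the channel engaged — the qualitative pattern the simulator
is built to explore.  Each configuration equilibrates quiescently (5 s) at
its own preload λ before stimulation, so the unstretched reference rests at
the intrinsic myocyte resting potential.

Measured consequences (computed by the test suite and acceptance script,
not assumed): 10–20% steady stretch elevates the single-cell resting
potential by ~6–7 mV; the effect saturates with λ because the resting point
moves onto the steep inward-rectifier branch.

## Myofilament model

Force generation follows a four-state cross-bridge / troponin-Ca scheme in
the Negroni–Lascano tradition: free troponin T, Ca-bound TCa, and two
attached force-generating states (TCa~ with calcium, T~ without), with
fluxes

    T + Ca ⇌ TCa            (Y1·Ca, Z1)
    TCa ⇌ TCa~              (Y2·Ov(L), Z2)      attachment, overlap-scaled
    TCa~ ⇌ T~ + Ca          (Y3, Z3·Ca)
    T~ → T                  (Y4)
    TCa~, T~ → detached     (Yd·(dX/dt)²)       strain-dependent detachment

The ensemble cross-bridge anchor X relaxes toward the isometric elongation
h_c: h = L − X, dX/dt = B(h − h_c); developed force F = A·h·(TCa~ + T~).
Filament overlap Ov(L) is a clipped parabola with optimum at L_opt.
[Ca²⁺]_i is an input — there is no feedback of mechanics on calcium or on
troponin affinity (out of scope by design).

**Parameter set (calibration artifact).**  The exact published rate
constants of the original formulation were not available to this project;
the values below keep the model's structure and are calibrated once so that
a 1-Hz human ventricular Ca transient produces a physiological isometric
twitch (peak ~90–150 ms after the Ca peak, back to within 2% of the
diastolic force pedestal before the next beat):

| constant | value | units | role |
|---|---|---|---|
| Tt | 0.07 | mM | total troponin sites |
| Y1 / Z1 | 39 / 0.03 | mM⁻¹ms⁻¹ / ms⁻¹ | Ca binding (K_d ≈ 0.77 µM) |
| Y2 / Z2 | 0.006 / 0.006 | ms⁻¹ | attachment / reversal |
| Y3 / Z3 | 0.06 / 0.8 | ms⁻¹ / mM⁻¹ms⁻¹ | Ca release from attached |
| Y4 | 0.04 | ms⁻¹ | detachment |
| Yd | 8000 | ms µm⁻² | strain-dependent detachment |
| B / h_c | 1.2 / 0.005 | ms⁻¹ / µm | anchor kinetics |
| L_opt / W | 1.12 / 0.45 | µm | overlap parabola |
| A | 24000 | f.u. µm⁻¹ mM⁻¹ | cross-bridge stiffness |

Force is reported in model force units (f.u.); the ventricle consumes force
through a single documented pressure-mapping constant, so the absolute
force scale is immaterial.  The myofilament ODEs share the 0.02 ms
electrophysiology step (they are far less stiff; halving the step moves
peak twitch force by < 1%).  Steady states under Ca clamp are verified
against an independent algebraic fixed-point solution.

## Ventricular geometry and mechanics

The wall is a **single layer** of circular fiber rings (default 24 rings ×
24 nodes) on a truncated prolate spheroid: ring i at polar angle θ_i ∈
[15°, 90°], unstressed radius r0_i = R_b sin θ_i, axial position
z0_i = −L_a cos θ_i, with R_b = 31 mm and L_a = 58 mm giving an unstressed
cavity volume of ~117 mL (human LV end-diastolic class).  Each ring is a
loop of identical half-sarcomeres in series, so its circumference fixes the
local half-sarcomere length HalfSL_i = C_i/N_i and stretch λ_i =
HalfSL_i/HalfSL0; along the outer (equatorial) boundary N = L_V0/HalfSL0.

Cavity volume comes from the solid of revolution of the ring radii.
Deformation is isotropic: radii and long axis scale together, so
λ = (V/V0)^(1/3) and the boundary length L_V = λ·L_V0.  (The real ventricle
shortens longitudinally as well as circumferentially; a fixed long axis
would force λ = (V/V0)^(1/2) and exaggerate fiber shortening further.)

Each beat runs a four-phase state machine at a 1 ms mechanics step:

* **isovolumic contraction** — volume frozen at the preload volume;
* **ejection** — when wall pressure reaches the arterial (Windkessel)
  pressure: flow Q = (P − P_art)/R_valve, 2-element Windkessel
  (R_p = 1000 mmHg·ms/mL, C = 2.5 mL/mmHg, initial P_art = 80 mmHg);
* **isovolumic relaxation** — when ejection flow reverses;
* **filling** — at constant filling pressure (10 mmHg) through a filling
  resistance, truncated at the prescribed preload stretch (fixed-preload
  protocol).

Cavity pressure is a lumped Laplace balance: the area-weighted mean ring
tension (active mean myofilament force per ring + exponential passive
tension k_p(e^{b_p(λ−1)} − 1), k_p = 0.007 f.u., b_p = 10, giving
end-diastolic pressures of ~10–25 mmHg over the preload range) divided by
the current stretch scale and mapped to mmHg by a single constant
(force_to_pressure = 400 mmHg/f.u.).  The mechanics constants were
calibrated **once** to a physiological control loop — peak pressure
~125 mmHg, ejection fraction ~0.47 — and then frozen; they were never
adjusted against electrophysiological outputs.

The λ field updates from the cavity volume at each mechanics step and is
used by the *following* electrophysiology steps (explicit, one-step-lagged
coupling): electro → force → volume/pressure → L_V → HalfSL → λ.  Per-ring
λ bookkeeping is retained although the uniform-scaling kinematics keep the
rings synchronous.

## Propagation

Isotropic monodomain propagation on the (ring × node) surface grid:
explicit finite-difference Laplacian, periodic circumferentially,
non-uniform second difference meridionally with no-flux closures at the
apex and base openings.  A CFL check guards every run and reports the
admissible step on violation.

The diffusion coefficient D and the tissue stimulus amplitude are not
physical inputs of the protocol but **calibration constants, tuned once and
frozen**: with the 6 ms apex-ring stimulus at resting length, the
stimulated element crosses −60 mV at 4.4 ms and total ventricular
activation completes in ~27 ms (the compact activation-to-recovery
dispersion of the target activation pattern).  The frozen values are
D = 4.0·10⁶ µm²/ms and 15.85 pA/pF.  The stimulus excites the full apex
ring (the apex "element" of a fiber-ring model), making activation
apex-symmetric.  The calibrated D is far above the physiological
~1.5·10⁵ µm²/ms because the grid is coarse (~2–4 mm spacing) and the model
ventricle must activate in tens of milliseconds from a single site without
a conduction system; consequently the electrotonic space constant is large
and repolarization is strongly synchronized across the wall.

## Heart failure

HF is six multiplicative factors on maximal conductances:
Ito ×0.25, IKs ×0.20, IK1 ×0.40, INa ×0.60, ICaL ×0.88, and Na⁺/Ca²⁺
exchange ×1.65 (`configs/hf_default.yaml`).  These are a **calibration
artifact**: the directions follow the standard human HF phenotype and the
magnitudes sit within experimentally reported ranges, chosen so the
remodeled cell shows clear 1-Hz AP prolongation and a reduced Ca transient.
Every HF result depends on them; editing the file invalidates the HF
acceptance checks.  Note the six factors exclude SERCA, which carries most
of the real HF contractile deficit, so the simulated HF loop depression is
modest.

## Markers

A single −60 mV threshold defines both markers: activation time = first
upward crossing after stimulus onset, recovery time = first downward
crossing after the AP peak (searching from the peak discards stimulus
artifacts), both linearly interpolated between samples; APD = RT − AT and
is reported as APD80 (−60 mV sits at ≈80% repolarization of this AP).
First crossing wins on multiple crossings.  Fibers that never recover
within the simulated window are flagged, excluded from extrema, and
counted.  Tissue voltage is sampled at 0.2 ms, bounding interpolation error
well below the reported precision.

## Synthetic fixture generator

`synthetic_ap_trace` emits piecewise-linear stylized APs with exactly known
AT/RT (and optional repolarization failure), used to test marker extraction
in isolation.  It emulates only the features the markers consume —
threshold crossings with controlled slopes — not AP morphology, rate
dependence, or noise; passing marker tests therefore demonstrate correct
crossing logic and interpolation, nothing about physiological traces.

## Problem sizes and determinism

Default runs: single cell, 5 s quiescent equilibration + 1.1 s beat;
ventricle, 24 × 24 nodes, 560 ms (control) / 800 ms (HF) beat at
Δt = 0.02 ms with 1 ms mechanics steps — a full ventricle beat computes in
seconds on one core (numba-compiled kernels).  There is no random number
generation anywhere: identical configurations produce bit-identical
outputs, and all protocol CSVs carry provenance headers (package version,
configuration hash, Δt).

## Known limitations

* **Single layer, no transmural heterogeneity** — one M-cell layer; epi/endo
  gradients and anisotropic, anatomically accurate conduction are out of
  scope.
* **Cell-model APD ceiling** — the M-cell's APD at the −60 mV threshold
  tops out near ~330 ms under any pacing history, which bounds the
  absolute tissue APD/RT values the simulator can produce.
* **SAC magnitudes** — with the reference SAC parameters the stretch
  effects are moderate (~6–7 mV resting elevation; no single-cell
  repolarization failure up to λ = 1.3); the repolarization-phase crossover
  of stretched vs unstretched traces occurs near the resting potential
  rather than at V_rev, because the traces differ in their takeoff states,
  not only in their SAC term.
* **Exaggerated fiber shortening** — the single-layer volume-to-λ mapping
  assigns all cavity-volume change to fiber strain (no wall thickening),
  so systolic λ dips well below 1 and silences the SAC through
  repolarization at moderate preloads.
* **Lumped hemodynamics** — phase-machine + Windkessel; no valves dynamics,
  atria, or inertance; the PV loop is physiological in class, not patient-
  specific.
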