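# Methods

## Scope and model reduction

The package analyses proximal pulmonary-artery (PA) hemodynamics with a
reduced-order (0D) surrogate of a compliant-wall, three-dimensional
fluid–structure simulation. Every quantity the pipeline calibrates or
reports — linearized wall stiffness E, distal totals R_T and C_T, relative
area change (RAC), pressure summaries, regurgitant volume, time-averaged
wall shear stress (TAWSS) — is expressible at 0D; spatial fields (wall
displacement maps, local WSS patterns, vortical structures) are outside the
model class and are not emulated.

## Network forward model

Each vessel segment (length L, end-diastolic radius r, wall thickness h)
contributes

- Poiseuille resistance R = 8μL/(πr⁴),
- blood-column inertance I = ρL/(πr²),
- wall compliance C = A_ed·L/(ρc_ed²), the per-unit-length area compliance
  dA/dP = A/(ρc²) integrated over the segment,

with the end-diastolic pulse-wave speed c_ed² = ζ·E·h/(ρ·r), ζ = 2/3. This
ζ is the Moens–Korteweg prefactor of an incompressible (ν = ½) thin
membrane: c² = E·h/(2ρr(1−ν²)) = (2/3)·E·h/(ρr). The same c_ed at the MPA
defines the characteristic impedance R_p = ρc_ed/A_MPA used as every
outlet's proximal Windkessel resistance.

Segment compliances are lumped half onto each end node (π-ladder). The
prescribed MPA inflow enters the root node; each leaf couples to an RCR
outlet (R_p, C, R_d) referenced to a distal pressure (default 0 mmHg,
configurable — the venous reference is a free choice of the study design
and all pressures shift with it).

### Viscoelastic wall

A purely elastic R–L–C ladder is almost lossless away from its terminations
and rings at its own inertance–compliance modes, which for physiologic PA
geometry fall near the second/third harmonic of the heart rate. Two
consequences are unphysical: pulse pressure acquires a fine non-monotone
ripple as a function of C_T, and the inverse problem develops spurious
near-roots (two parameter sets reproducing the same systolic/diastolic
pressures). Arterial walls are viscoelastic, and wall viscosity is exactly
the mechanism that damps these modes, so each node's wall compliance is
split: a fraction (1 − φ) responds instantaneously and a fraction φ through
a series resistance R_w = τ_w/(φC) (a Voigt element). Defaults: φ = 0.5,
τ_w = 8 ms, a typical arterial wall relaxation time; τ_w = 0 restores the
elastic wall. The damping is invisible at steady state and weak at the
fundamental frequency (ωτ_w ≈ 0.07), so mean pressures, RAC and pulse
physics are essentially unchanged while the in-band ringing is suppressed.

### Time integration and periodicity

The system is linear, M ẋ = K x + f(t), with states [node pressures,
branch flows, outlet capacitor pressures, retarded wall pressures]. It is
advanced with a fixed-step trapezoidal rule (A-stable, second order;
outlet RC products can be much shorter than the period, so stiff-safety
matters) at 512 steps per cycle by default; halving the step changes
P_sys, P_dias and RAC by well under 0.5%. Cycles repeat from a warm start
(uniform mean pressure, area-share branch flows) until the maximum change
of the MPA pressure trace between successive cycles falls below 10⁻³
relative, typically 5–15 cycles; non-convergence raises an error rather
than returning a drifting solution.

### Derived markers

- Pressure summary: P_sys/P_dias are the extrema of the MPA (root node)
  trace, P̄ its time average.
- Areas: A(t) = A_ed(1 + (P_w − P_ref)/(ρc_ed²)) per segment, where P_w is
  the effective wall-charge pressure (instantaneous + retarded parts) at
  the segment's inlet node and P_ref is its diastolic minimum over the
  final cycle. Anchoring P_ref at the diastolic minimum makes the
  end-diastolic area equal the reconstruction geometry exactly, keeps
  A(t) > 0 by construction, and gives RAC = (A_max − A_min)/A_min its
  measured meaning.
- TAWSS: Poiseuille surrogate τ(t) = 4μ|Q(t)|/(πr³) per segment, cycle
  averaged; aggregates (MPA only, or the whole tree — the averaging subset
  is explicit) weight segments by luminal surface area 2πrL. Absolute 0D
  TAWSS values underestimate 3D values (no secondary flows, blunt-profile
  effects); between-group ordering and correlations are the meaningful
  outputs.
- Regurgitant volume: ∫max(−Q,0)dt of the measured inflow, with zero
  crossings located by linear interpolation (exact for piecewise-linear
  waveforms).

## Boundary-condition derivation and outlet split

Initial totals come from the flow features and target pressures,
R_T = P̄/Q̄ and C_T = (Q̇max − Q̇min)·Δt/ΔP, where Δt is measured forward in
time from the global flow maximum to the next global minimum (wrapping
periodically), matching the systolic-peak-to-post-systolic-trough reading
of PA waveforms. The split assumes equal left/right flow, then distributes
conductance and compliance within each side proportionally to outlet area,
with A_T interpreted as the *per-side* total outlet area — the only reading
under which the equal split and the exact recovery of R_T and C_T hold
simultaneously (conservation is exact to machine precision and is tested
to 10⁻¹² over randomized trees).

Blood: ρ = 1060 kg/m³, μ = 0.004 Pa·s (Newtonian), both configurable.
Wall: ν = 0.5; thickness from h = coefficient·d with coefficient 0.05
(thickness = 10% of radius) where no explicit thickness is given — the
calibration adjusts E, so E·h is the effective stiffness parameter and the
coefficient choice is absorbed.

## Inverse calibration

Targets are (RAC, P_sys, P_dias). Two nested fixed-point loops:

- Outer (stiffness): E ← E·(RAC_model/RAC_target)^α with under-relaxation
  α = 0.7. With pressures pinned by the inner loop, RAC ≈ ΔP/(ρc_ed²) ∝ 1/E,
  so the update has unit sensitivity and converges geometrically.
- Inner (totals), at fixed E: R_T ← R_T·(m_t − P_ref)/(m_m − P_ref) with
  m = (P_sys + 2P_dias)/3 evaluated identically on target and model
  pressures (so a self-consistent target set is an exact fixed point), and
  a C_T update that is multiplicative, C_T·(ΔP_m/ΔP_t), on the first step
  and a measured-slope secant on log ΔP vs log C_T afterwards, with steps
  clipped to a factor of 4. R_p, c_ed and the outlet split are re-derived
  from the current E every iteration.

Identifiability guards: the C_T search is confined below the network's
fundamental resonance (cap 0.25/(ω₁²·L_eff), with L_eff the root-to-outlet
inertance combined in parallel over branches), excluding a spurious
frozen-capacitor regime that can reproduce the scalar pressure targets
with an unphysiologically slow diastolic decay. Loops exit when all
residuals meet the relative tolerance (default 1%), but keep polishing
while residuals still improve (down to a third of the tolerance, stall =
two consecutive iterations with <5% improvement): the true root has zero
residual, and first-touch exits would leave C_T errors near the tolerance
boundary in the flat-sensitivity regime (C_T ≪ proximal tree compliance).
Everything is deterministic; the convergence log records every forward
evaluation.

Observed performance on self-consistent synthetic subjects from ×2/÷2
perturbed starts (the regime the tests measure): E within ~1%, R_T within
~0.5%, C_T within ~4%.

## Synthetic subjects

The generator defines the study conditions; targets for each subject come
from a forward run at that subject's true parameters, so the inverse
pipeline is always scored against known ground truth.

- Waveform: half-sine systolic lobe over a systolic fraction of 0.35, a
  raised-cosine diastolic plateau carrying 8% of the stroke volume, and —
  for PAH-like subjects — a post-systolic negative half-sine lobe spanning
  0.15 of the period. Phase boundaries snap to the sample grid so the
  positive/negative parts can be rescaled separately to exact volumes:
  forward volume = stroke volume, retrograde volume = f_reg·SV. Optional
  multiplicative noise precedes the rescale and cannot flip sample signs.
- Regurgitant fraction is coupled to the true stiffness,
  f_reg = 0.02 + 0.0004·(E/kPa − 100) clipped to [0, 0.3], so the
  stiffness–regurgitation association is a recoverable pipeline output: it
  must re-emerge from *calibrated* E, not be assumed.
- Trees: MPA at the archetype diameter, LPA/RPA at taper 0.72, two further
  generations at taper 0.78 with 5% lognormal radius jitter (depth
  configurable), thickness from the linear rule.
- Archetype centres — control: E 75 kPa, R_T 3.99 mmHg·min/l,
  C_T 0.85 ml/mmHg, D 25 mm, SV 69 ml, HR 81/min, f_reg 0; PAH: E 300 kPa,
  R_T 6.89, C_T 0.13, D 32 mm, SV 71 ml, HR 71/min. Dispersion is
  lognormal with 15% coefficient of variation for E/R_T/C_T, 10% for the
  period, 15% for stroke volume and 6% for diameter (the tighter diameter
  spread reflects the narrow anatomic range of MPA calibre relative to the
  hemodynamic parameters).

What the generator does *not* emulate: imaging noise and segmentation
variability, beat-to-beat variability, waveform morphologies beyond the
lobe family, pressure-dependent (nonlinear) wall stiffening, and any 3D
flow feature. Passing tests therefore demonstrate internal consistency of
the calibration chain and the statistics under realistic parameter ranges,
not agreement with any particular patient data.

## Statistics

Median and IQR use linear interpolation of order statistics (so
{1,2,3,4,5} → Q1 = 2, Q3 = 4). The Mann–Whitney U test uses midranks for
ties; for pooled sizes ≤ 14 the two-sided p-value is exact, defined as the
doubled lower tail min(1, 2·P(U ≤ u_obs)) with u_obs = min(U_x, U_y),
enumerated over all C(n_x+n_y, n_x) labelings; larger samples use a
tie-corrected normal approximation with continuity correction. Spearman's
r is the Pearson correlation of midranks; for n ≤ 8 the two-sided p-value
enumerates all n! pairings, p = P(|r_perm| ≥ |r_obs|); larger n uses the
Student-t approximation with n − 2 degrees of freedom. The significance
threshold is stored as 0.050. No multiple-testing correction is applied.

## Numerical choices and degenerate inputs

- Tolerance ladder: cycle periodicity 10⁻³ (relative), calibration residual
  10⁻² per target, conservation of the outlet split is exact algebra.
- Waveforms require ≥ 16 samples per period, strictly increasing times,
  t₀ = 0 and t_last < T (the wrap value is the first sample).
- A RAC target of 0 with nonzero pulse pressure is rejected as infeasible
  (a compliant wall cannot produce it); constant vectors are rejected by
  the correlation test rather than silently returning 0.
- An outlet whose total resistance does not exceed the characteristic
  impedance is reported with the offending outlet id.
- Exact floating-point comparisons in the enumeration tests carry a 10⁻⁹
  guard for tied rank sums.

## Known limitations

- The 0D surrogate has no wave propagation; pressure is spatially uniform
  per node, so "MPA pressure" means the inflow-plane node.
- With the default distal reference of 0 mmHg and small C_T, diastolic
  pressures can decay further than typical catheterization traces; setting
  the reference to a venous/wedge-like value shifts the operating point.
- Absolute TAWSS levels are Poiseuille estimates; only relative patterns
  are interpretable.
- The calibration assumes RAC decreases with E and pulse pressure decreases
  with C_T within the searched region; both are enforced/verified, but
  pathological trees (extreme tapers) outside the generator's range could
  violate the resonance-cap heuristic.
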