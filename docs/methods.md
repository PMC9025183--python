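# Methods

`fddflow` reproduces, at desk scale and on idealized two-dimensional
geometries, the computational workflow used to assess endothelialization
risk after virtual flow-diverter (FDD) deployment in cerebral aneurysms:
incompressible hemodynamics with a porous-medium stent model and mixed
Newtonian/Casson rheology, followed by wall-shear-stress (WSS) risk
metrics and a two-threshold clinical-outcome rule.  This note records the
model, its assumptions, the numerical choices, and what the idealized
setting can and cannot show.

## Flow model

Blood is an incompressible fluid with density ρ = 997 kg/m³.  The solver
discretizes the Navier–Stokes equations with Taylor–Hood (P2 velocity /
P1 pressure) triangular finite elements, in two coordinate modes:

* **axisymmetric** (z–r half plane of a circular tube) — used for the
  Poiseuille-profile validation; the weak form carries the r dr dz
  measure, the hoop stress term 2μu_r v_r/r² and the u_r/r divergence
  contribution, with u_r = 0 on the axis;
* **planar 2-D** (unit depth) — used for the parent-vessel +
  sidewall-aneurysm scenarios.

Boundary conditions follow the clinical setting being emulated: a uniform
(plug) velocity at the inlet, no-slip rigid walls, and "opening" outlets
modelled as zero normal traction with the sign of the normal velocity left
free, so local vortices may draw fluid back in without aborting the solve.
Viscous stresses use the full symmetric gradient μ(∇u + ∇uᵀ), which makes
the natural outlet condition traction-free.

The steady solver iterates Picard sweeps (three) followed by Newton
linearization of the convective term, with Aitken Δ² relaxation to
accelerate the linearly convergent viscosity fixed point contributed by
the Casson dome; convergence is declared when the relative velocity
increment falls below 10⁻⁸ (configurable), and non-convergence raises an
error carrying the increment history.  Each linearized saddle system is
solved with a sparse direct factorization.  The pulsatile solver uses
backward-Euler steps of dt = 0.01 s over a 3 s window (three repeats of a
1 s cardiac cycle, 300 steps), each step iterated to a 10⁻⁵ relative
increment; the run starts from the steady solution at the cycle-start
inlet speed, transients decay during the first cycles, and analysis is
restricted to the final second, where the named cycle points
t1 = 2.03 s, t2 = 2.25 s, t3 = 2.36 s, t4 = 2.70 s live (t2/t3 systolic,
t1/t4 diastolic).

Because continuity is enforced weakly against every P1 test function, the
discrete inflow/outflow balance holds to linear-solver roundoff at every
steady solve and every pulsatile step; the conservation tests observe
imbalances at the 10⁻¹³ level against their 0.5 % bound.

The plug inlet conflicts with no-slip at the inlet corner; the wall value
wins there, so the realized inlet flux is O(h) below the nominal plug
flux (≈4 % at the default tube resolution).  All profile comparisons and
convergence checks therefore normalize by the *measured* bulk velocity,
never the nominal plug value.

## Rheology

The mixed setting assigns Newtonian viscosity μ₀ = 0.004 Pa·s to the
parent lumen and stent region and the Casson effective viscosity

  μ(γ̇) = (√(τ₀/γ̇) + √μ₀)²,  τ₀ = μ₀ = 0.004 Pa·s (0.04 in CGS units)

to the aneurysm dome, where shear rates are low.  The scalar shear rate is
the second invariant in its plain form γ̇ = √(ε_ij ε_ij) with
ε = (∇u + ∇uᵀ)/2; the common √(2 ε:ε) convention is available as a
configuration switch but off by default.  The law is singular at γ̇ = 0,
so γ̇ is floored at `gamma_floor` = 10⁻³ s⁻¹ before evaluation (the
quiescent dome then sees a finite viscosity cap of ≈4.3 Pa·s); μ is
strictly decreasing in γ̇ and bounded below by μ₀.  The floor value is a
regularization choice: it only matters where the flow is nearly stagnant,
and the reported metrics live on surfaces where shear is finite.

## Porous stent model

The deployed stent occupies a cell set of the *fixed* mesh — deployment
relabels cells, never remeshes — and acts through the Brinkman body force
F = −D μ u per unit volume, with the Forchheimer (quadratic) term
identically zero because stent-region velocities are small.  Scenarios:

* **A (plug)** — a thin porous layer (two cell layers by default) covering
  the aneurysm neck; isotropic D = d·I.
* **B (small-cell tube)** — a wall-adjacent layer of the given thickness
  (0.8 mm default) spanning the neck ± one neck width; normal-aligned
  D = d·n⊗n with n the unit normal of the nearest stent-surface facet
  (nearest-facet lookup, ties to the smallest facet index), so only flow
  *crossing* the stent is damped.
* **C (wide-mesh tube)** — the same layer with isotropic D.

The magnitude d is nominally the inverse permeability (1/m²).  Taken
literally as a "unit tensor", d = 1 m⁻² is a physically negligible sink at
SI scale, so the default is calibrated once on the reference idealized
geometry: d = 9×10⁷ m⁻² makes the scenario-A plug reduce steady neck
inflow by ≈18 %, the reduction scale reported for successful clinical
deployments.  The literal value remains selectable.

Two properties of the sink are worth recording honestly:

* d → 0 recovers the preoperative momentum equation exactly for
  scenarios B/C, whose stent cells are carved from the Newtonian lumen.
  Scenario A additionally reclassifies plug cells from Casson (dome) to
  Newtonian rheology, a deliberate modelling choice, so its d → 0 limit
  differs from the preoperative solve by that rheology change.
* Neck inflow is *not* globally monotone in d on this geometry: at
  sub-operative damping (d ≈ 10⁷ m⁻²) the tube scenarios narrow the
  effective lumen, strengthen the driving shear layer and transiently
  *increase* neck exchange before the sink dominates.  From the calibrated
  operative value upward (the sweep d × {1, 10, 10², 10³, 10⁴} used in the
  acceptance suite) inflow decreases monotonically, and at the default d
  every scenario reduces inflow relative to the preoperative case.

## Geometry and the synthetic-data stage

The geometry module is the synthetic-data generator: it emulates the
study conditions, not patient anatomy.  The reference domain is a planar
parent channel of half-width 2 mm (ICA scale) and length 20 mm with a
sidewall sac of radius 3 mm opening across a 2 mm neck — the sac is the
major circular segment over the neck chord, meshed with a Delaunay
triangulation (hexagonal interior lattice) that conforms exactly to the
channel grid along the chord.  The validation tube has radius 2 mm and
length 20 mm.  All dimensions are configurable.  Preoperative and stented
meshes for one specification share the identical node set and surface
facets, which is what makes the per-cell difference

  ΔWSS = WSS_after − WSS_before

exact with no resampling.  What the idealized setting does **not**
emulate: 3-D patient vasculature, vessel curvature and tapering, strut-
resolved stent geometry, wall compliance (FSI), or thrombosis chemistry.
Passing tests certify the numerics and the metric/classification
pipeline, not patient-specific predictions; the patient-scale Max ΔWSS
magnitudes of the clinical study are not reproducible at desk scale.

## Metrics

WSS is the magnitude of the tangential viscous traction μ(∇u + ∇uᵀ)·n at
the facet midpoint of a surface cell, evaluated with the local (possibly
Casson) cell viscosity; on interior measurement surfaces (neck, stent
face) the lumen-side cell supplies the gradient.  ΔWSS is the signed
per-cell difference post − pre.  The parent wall is partitioned into
before / at / after-the-neck compartments (boundaries at the neck edges);
the Max ΔWSS series is taken over the working section (at + after), the
percent-of-cells histograms default to 20 uniform bins over the observed
range, and RSI — the area-averaged shear, (Σ τ_c A_c)/(Σ A_c), equal to
total shear force over area — is computed for the ΔWSS field on the stent
surface.  Neck inflow integrates ρ·max(u·n, 0) over the neck (n into the
dome), reported in g/s (per metre of depth in planar mode); the signed
net flux is reported alongside.

## Statistics and outcome rule

Profile validation samples the axial velocity one diameter downstream of
the inlet and forms the Pearson statistic χ² = Σ (v_num − v_exact)²/v_exact
against the analytic Poiseuille profile v(r) = (P1−P2)(R²−r²)/(4Lη), with
the pressure drop eliminated via the measured flow rate.  The wall
station (zero expectation) is excluded; dof defaults to retained stations
minus one and may be given explicitly (the reference checks use 60 dof
for 61 stations and 49 dof for 50 core stations).  χ² on dimensional
velocities is unit-sensitive, so a peak-normalized variant is available.
Normality (Shapiro–Wilk) and two-sample distribution comparison
(Kolmogorov–Smirnov) delegate to vetted SciPy routines.

The outcome rule reduces the cycle series of Max ΔWSS at t1…t4, rounded
to two decimals, to one label: cycle minimum > 1.23 Pa → in-stent
**stenosis** (endothelial over-proliferation); otherwise cycle maximum
< 1.68 Pa → **no occlusion** (insufficient endothelialization); otherwise
**norm**.  This min/max reading is the unique simple rule consistent with
the four reference outcome series and both threshold
inequalities; thresholds, rounding and rule are configurable.

## Problem sizes and determinism

Default study sizes: tube at 0.25 mm resolution (≈1 300 cells, ≈12 000
velocity+pressure unknowns), aneurysm studies at 0.3–0.5 mm (≈1 000–2 500
cells); the acceptance checks use these sizes and complete in seconds to
a few minutes on one core.  Every stage is deterministic for a fixed
configuration — meshing, assembly ordering, direct solves and tie-breaks
contain no randomness — so repeated runs produce bit-identical metric
tables.

## Known limitations

* Planar 2-D scenarios transfer the qualitative behaviour (inflow
  reduction, ΔWSS concentration at the neck), not patient-scale numbers;
  fluxes in planar mode are per metre of depth.
* The plug-inlet corner treatment biases the realized flux by O(h);
  normalize by measured flux when comparing across resolutions.
* The scenario-B normal field comes from nearest-facet lookup and is
  piecewise constant; strongly curved stent surfaces would need a
  smoother normal reconstruction.
* Backward Euler is first-order in time; dt = 0.01 s is fixed by the
  emulated protocol rather than by an error controller.
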