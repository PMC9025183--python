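# fddflow

Desk-scale hemodynamics of virtual flow-diverter deployment in cerebral
aneurysms.

Flow-diverter devices (FDDs) treat cerebral aneurysms by redirecting flow
past the aneurysm neck; success hinges on endothelialization of the stent
— too vigorous and the lumen narrows (in-stent stenosis), too weak and the
aneurysm never occludes.  Endothelial proliferation is governed by the
*change* in wall shear stress, so the quantity of interest is the per-cell
difference before/after virtual deployment,

    ΔWSS = WSS_after − WSS_before ,

its cycle maxima at four cardiac time points (t1 = 2.03, t2 = 2.25,
t3 = 2.36, t4 = 2.70 s of a 3 s, dt = 0.01 s pulsatile run), the
area-averaged shear over the stent surface RSI = (∫∫_S τ dS)/S, and a
two-threshold outcome rule: cycle min > 1.23 Pa ⇒ stenosis; cycle max
< 1.68 Pa ⇒ no occlusion; otherwise normal healing.

`fddflow` implements this workflow end to end on idealized 2-D geometries
(for whom: researchers studying FDD hemodynamic risk metrics who need a
transparent, fully scriptable desk-scale counterpart to patient-specific
CFD):

* parameterized meshes — straight tube (axisymmetric) for validation, a
  parent vessel + sidewall aneurysm for the scenarios; the stent is
  deployed by relabelling cells of a fixed mesh, so pre/post surfaces are
  cell-identical and ΔWSS is exact;
* a porous-medium (Brinkman) stent model, F = −D μ u, with three scenario
  geometries: neck plug (A, isotropic), wall-adjacent tube with
  normal-aligned damping (B) or isotropic damping (C);
* mixed rheology: Newtonian lumen, Casson aneurysm dome
  μ = (√(τ₀/γ̇) + √μ₀)² with τ₀ = μ₀ = 0.04 dyne·s/cm²;
* a Taylor–Hood (P2/P1) incompressible solver, steady and pulsatile, with
  plug inlet, no-slip walls and free-backflow "opening" outlets;
* metrics and statistics: WSS/ΔWSS extraction, RSI, neck inflow,
  percent-of-cells histograms, Pearson goodness of fit against the
  analytic Poiseuille profile v(r) = (P1−P2)(R²−r²)/(4Lη), Shapiro–Wilk
  and Kolmogorov–Smirnov tests, and the outcome classifier.

See `docs/methods.md` for the model details and design choices.

## Worked example

Validate that a parabolic profile establishes one diameter downstream of a
uniform inlet (the standard check that a plug inlet suffices), then
classify a measured Max ΔWSS cycle series:

```sh
$ fddflow validate-profile --resolution 0.00025 --stations 61 --dof 60
{
  "chi2": 0.05238296109744473,
  "p_value": 1.0,
  "dof": 60,
  "stations": 61
}
```

The tube solve (radius 2 mm, length 20 mm, inlet 0.06 m/s, μ = 0.004
Pa·s) is sampled at 61 radial stations one diameter from the inlet; the
Pearson χ² of 0.05 against the flow-rate-matched Poiseuille profile is
far below the 60-dof acceptance region, p ≈ 1.0 — the uniform inlet has
fully developed.

```sh
$ printf 't1,t2,t3,t4\n1.141,1.677,1.660,1.226\n' > series.csv
$ fddflow classify series.csv
[
  {
    "t1": 1.141,
    "t2": 1.677,
    "t3": 1.66,
    "t4": 1.226,
    "outcome": "NORM"
  }
]
```

The series' cycle minimum (1.14 Pa) does not exceed the stenosis
threshold 1.23 Pa, and its maximum rounds to 1.68 Pa, which is not below
the occlusion threshold — the stent is predicted to heal normally.

A full run (geometry → pre/post solves → metrics → classification) is
driven by one YAML file:

```yaml
# run.yaml
geometry: {scenario: A, resolution: 0.0004}
waveform: {scale: 1.0}        # reference carotid waveform
outdir: out_A
```

```sh
fddflow pipeline --config run.yaml
```

which writes meshes and field snapshots (VTU), `metrics.csv` (Max ΔWSS,
RSI force/area series, inflow) and `report.json` with the outcome label.
Library use mirrors the CLI: see `fddflow.pipeline.run_pipeline` and the
module-level functions re-exported from `fddflow`.

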