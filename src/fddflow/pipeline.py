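"""End-to-end virtual-stenting pipeline.

One configuration drives the whole workflow: build the idealized
parent-vessel + aneurysm mesh, deploy the chosen stent scenario by cell
relabelling, solve the preoperative and stented flows (steady, and
pulsatile over three cardiac cycles), extract WSS and its pre/post
difference on the shared surfaces, and reduce to the outcome metrics —
Max dWSS at the four cycle points, the RSI series, neck inflow, surface
histograms and the two-threshold outcome label.  All artifacts are written
to the output directory together with a manifest; runs are deterministic
for a fixed configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .geometry import (GeometrySpec, Scenario, STENT_SURFACE, WALL,
                       embed_stent_region, make_sidewall_aneurysm)
from .hemodynamics import (SolverConfig, TIME_POINTS, Waveform,
                           build_reference_waveform, scale_waveform,
                           solve_pulsatile, solve_steady)
from .metrics import (aneurysm_inflow, delta_wss, histogram_percent,
                      max_delta_wss, rsi, wall_compartment_mask,
                      wall_shear_stress)
from .porous import PorousSpec
from .rheology import RheologyParams
from .stats import ClassifierConfig, classify_outcome


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Everything one run needs; see the YAML keys of :func:`load_config`."""

    geometry: GeometrySpec = field(default_factory=lambda: GeometrySpec(
        scenario=Scenario.A))
    rheology: RheologyParams = field(default_factory=RheologyParams)
    porous: Optional[PorousSpec] = None
    solver: SolverConfig = field(default_factory=SolverConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    waveform: Optional[Waveform] = None
    waveform_scale: float = 1.0
    outdir: Path = Path("fddflow_out")
    run_pulsatile: bool = True
    histogram_bins: int = 20

    def __post_init__(self) -> None:
        if self.geometry.scenario == Scenario.NONE:
            raise PipelineError("pipeline needs a stent scenario (A/B/C)")
        if self.porous is None:
            self.porous = PorousSpec(scenario=self.geometry.scenario)
        if self.waveform is None:
            self.waveform = scale_waveform(build_reference_waveform(),
                                           self.waveform_scale)
        self.outdir = Path(self.outdir)


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Recognized top-level keys: geometry, rheology (``cgs: true`` reads the
    viscosity constants in dyne*s/cm^2), porous, solver, classifier,
    waveform (``csv`` or ``anchors``/``scale``), outdir, run_pulsatile,
    histogram_bins.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw: dict = {}
    g = dict(raw.get("geometry", {}))
    if "scenario" in g:
        g["scenario"] = Scenario[str(g["scenario"]).upper()]
    kw["geometry"] = GeometrySpec(**g)
    r = dict(raw.get("rheology", {}))
    if r.pop("cgs", False):
        kw["rheology"] = RheologyParams.from_cgs(**r)
    elif r:
        kw["rheology"] = RheologyParams(**r)
    p = dict(raw.get("porous", {}))
    if p:
        p["scenario"] = Scenario[str(p.get(
            "scenario", kw["geometry"].scenario.name)).upper()]
        kw["porous"] = PorousSpec(**p)
    if raw.get("solver"):
        kw["solver"] = SolverConfig(**raw["solver"])
    if raw.get("classifier"):
        kw["classifier"] = ClassifierConfig(**raw["classifier"])
    w = raw.get("waveform", {})
    if "csv" in w:
        kw["waveform"] = fio.read_waveform_csv(w["csv"], w.get("period"))
    elif "anchors" in w:
        kw["waveform"] = build_reference_waveform(w["anchors"])
    kw["waveform_scale"] = float(w.get("scale", 1.0))
    for key in ("outdir", "run_pulsatile", "histogram_bins"):
        if key in raw:
            kw[key] = raw[key]
    return PipelineConfig(**kw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the report dict (also on disk)."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": 1, "artifacts": [], "stages": []}

    def emit(name: str):
        manifest["artifacts"].append(name)

    # --- geometry ---------------------------------------------------------
    try:
        spec_pre = GeometrySpec(**{**_spec_kwargs(config.geometry),
                                   "scenario": Scenario.NONE})
        mesh_pre = make_sidewall_aneurysm(spec_pre)
        mesh_post = embed_stent_region(
            mesh_pre, config.geometry.scenario,
            None if config.geometry.scenario == Scenario.A
            else config.geometry.stent_thickness,
            extent=config.geometry.stent_extent)
        mesh_pre.validate()
        mesh_post.validate()
    except Exception as e:
        raise PipelineError(f"stage 'geometry' failed: {e}") from e
    manifest["stages"].append("geometry")
    fio.write_mesh(out / "mesh_pre.vtu", mesh_pre)
    fio.write_mesh(out / "mesh_post.vtu", mesh_post)
    emit("mesh_pre.vtu")
    emit("mesh_post.vtu")

    rheo = config.rheology
    u_mean = float(np.mean(config.waveform.velocities))

    # --- steady solves ----------------------------------------------------
    try:
        steady_pre = solve_steady(mesh_pre, rheo, porous=None,
                                  inlet_speed=u_mean, config=config.solver)
        steady_post = solve_steady(mesh_post, rheo, porous=config.porous,
                                   inlet_speed=u_mean, config=config.solver)
    except Exception as e:
        raise PipelineError(f"stage 'steady-solve' failed: {e}") from e
    manifest["stages"].append("steady-solve")
    fio.write_mesh(out / "steady_pre.vtu", mesh_pre, steady_pre)
    fio.write_mesh(out / "steady_post.vtu", mesh_post, steady_post)
    emit("steady_pre.vtu")
    emit("steady_post.vtu")

    inflow_pre = aneurysm_inflow(steady_pre, mesh_pre, rheo.rho)
    inflow_post = aneurysm_inflow(steady_post, mesh_post, rheo.rho)

    # --- pulsatile solves + metrics at t1..t4 -----------------------------
    def metrics_at(tp, fpre, fpost):
        wall_pre = wall_shear_stress(fpre, mesh_post, WALL)
        wall_post = wall_shear_stress(fpost, mesh_post, WALL)
        d_wall = delta_wss(wall_pre, wall_post)
        # working section of the parent wall: at and beyond the neck
        sel = (wall_compartment_mask(mesh_post, d_wall.facets, "at")
               | wall_compartment_mask(mesh_post, d_wall.facets, "after"))
        dwss_fields[tp] = type(d_wall)(
            facets=d_wall.facets[sel], dwss=d_wall.dwss[sel],
            areas=d_wall.areas[sel], surface_tag=d_wall.surface_tag,
            t=d_wall.t)
        s_pre = wall_shear_stress(fpre, mesh_post, STENT_SURFACE)
        s_post = wall_shear_stress(fpost, mesh_post, STENT_SURFACE)
        r = rsi(delta_wss(s_pre, s_post))
        rsi_rows.append({"time_point": tp, "time": TIME_POINTS[tp],
                         "force_N": r.force, "area_m2": r.area,
                         "rsi_Pa": r.rsi})

    rsi_rows: list[dict] = []
    dwss_fields: dict = {}
    if config.run_pulsatile:
        try:
            puls_pre = solve_pulsatile(mesh_pre, rheo, None, config.waveform,
                                       config=config.solver, store_from=2.0)
            puls_post = solve_pulsatile(mesh_post, rheo, config.porous,
                                        config.waveform,
                                        config=config.solver, store_from=2.0)
        except Exception as e:
            raise PipelineError(f"stage 'pulsatile-solve' failed: {e}") from e
        manifest["stages"].append("pulsatile-solve")
        for tp in ("t1", "t2", "t3", "t4"):
            metrics_at(tp, puls_pre.at_named(tp), puls_post.at_named(tp))
    else:
        # steady fallback: the four time points share the steady fields
        for tp in ("t1", "t2", "t3", "t4"):
            metrics_at(tp, steady_pre, steady_post)
    manifest["stages"].append("metrics")

    max_series = max_delta_wss(dwss_fields)
    outcome = classify_outcome(max_series, config.classifier)
    edges, percent = histogram_percent(dwss_fields["t2"],
                                       n_bins=config.histogram_bins)

    metrics_df = pd.DataFrame(rsi_rows)
    metrics_df["max_dwss_Pa"] = [max_series[tp]
                                 for tp in ("t1", "t2", "t3", "t4")]
    metrics_df.to_csv(out / "metrics.csv", index=False,
                      float_format="%.10g")
    emit("metrics.csv")

    report = {
        "scenario": config.geometry.scenario.name,
        "outcome": outcome.value,
        "max_dwss": {k: float(v) for k, v in max_series.items()},
        "rsi": {row["time_point"]: row["rsi_Pa"] for row in rsi_rows},
        "inflow": {"pre_g_per_s": inflow_pre["inflow"],
                   "post_g_per_s": inflow_post["inflow"],
                   "pre_net_g_per_s": inflow_pre["net"],
                   "post_net_g_per_s": inflow_post["net"]},
        "steady": {
            "pre_picard_iterations":
                len(steady_pre.diagnostics["picard_history"]),
            "post_picard_iterations":
                len(steady_post.diagnostics["picard_history"]),
            "pre_div_residual": steady_pre.diagnostics["div_residual"],
            "post_div_residual": steady_post.diagnostics["div_residual"],
        },
        "thresholds": {
            "theta_stenosis": config.classifier.theta_stenosis,
            "theta_occlusion": config.classifier.theta_occlusion},
        "histogram": {"edges_Pa": edges.tolist(),
                      "percent": percent.tolist()},
    }
    fio.write_report(out / "report.json", report)
    emit("report.json")
    manifest["stages"].append("report")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _spec_kwargs(spec: GeometrySpec) -> dict:
    return {f: getattr(spec, f) for f in (
        "parent_radius", "parent_length", "dome_radius", "neck_width",
        "stent_thickness", "scenario", "resolution", "stent_extent")}
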