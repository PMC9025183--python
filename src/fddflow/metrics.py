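"""Endothelialization-risk metrics from converged flow fields.

Wall shear stress (WSS) is the magnitude of the tangential viscous traction
mu*(grad u + grad u^T).n on a surface cell, evaluated with the local
(possibly Casson) viscosity.  The per-cell signed difference

    dWSS = WSS_after_deployment - WSS_before_deployment

is the quantity linked to clinical outcome: its cycle maxima at the named
time points feed the two-threshold classifier, its surface distribution the
percent-of-cells histograms, and its area average over the stent surface
the RSI (area-averaged shear, Eq.-style surface integral of tau over S
divided by S).  dWSS is only defined because preoperative and stented
meshes share the identical surface discretization; mismatched surfaces
raise instead of being resampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from . import _fem
from .geometry import Mesh, Region, WALL
from .hemodynamics import FlowField


class MetricError(ValueError):
    """Raised on inconsistent metric inputs."""


@dataclass
class WSSField:
    """Unsigned shear-stress magnitude per surface cell (Pa)."""

    facets: np.ndarray
    tau: np.ndarray
    areas: np.ndarray
    surface_tag: str
    t: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.areas <= 0):
            raise MetricError("surface cell areas must be positive")
        if np.any(self.tau < 0):
            raise MetricError("WSS is a magnitude; negative value found")


@dataclass
class DeltaWSSField:
    """Signed per-cell WSS difference (post - pre) on a shared surface."""

    facets: np.ndarray
    dwss: np.ndarray
    areas: np.ndarray
    surface_tag: str
    t: float = 0.0


@dataclass
class RSIResult:
    """Area-averaged shear over a surface: force = sum tau*A, rsi = force/area."""

    force: float
    area: float
    rsi: float
    t: float = 0.0


def _facet_cells(mesh: Mesh, facets: np.ndarray) -> np.ndarray:
    """For each facet the adjacent cell used for gradient evaluation:
    the unique cell for boundary facets, the lumen-side (non-STENT,
    non-DOME preferred) cell for interior surfaces."""
    want = {}
    for idx, (a, b) in enumerate(facets):
        k = (min(int(a), int(b)), max(int(a), int(b)))
        want[k] = idx
    found: dict[int, list[int]] = {}
    for ci, tri in enumerate(mesh.cells):
        for i in range(3):
            a, b = int(tri[i]), int(tri[(i + 1) % 3])
            k = (a, b) if a < b else (b, a)
            if k in want:
                found.setdefault(want[k], []).append(ci)
    out = np.empty(len(facets), dtype=np.int64)
    rank = {int(Region.LUMEN): 0, int(Region.DOME): 1, int(Region.STENT): 2}
    for idx in range(len(facets)):
        cs = found.get(idx)
        if not cs:
            raise MetricError("facet not part of the mesh")
        cs = sorted(cs, key=lambda c: (rank[int(mesh.cell_region[c])], c))
        out[idx] = cs[0]
    return out


def wall_shear_stress(flow: FlowField, mesh: Mesh, surface_tag: str = WALL,
                      ) -> WSSField:
    """Per-facet magnitude of the tangential viscous traction.

    ``surface_tag`` may name an outer boundary (WALL) or an interior
    measurement surface (NECK, STENT_SURFACE); for interior surfaces the
    velocity gradient is taken from the lumen-side cell.  The local cell
    viscosity of the solve is used, so Casson thinning in the dome carries
    through to the stress.
    """
    if surface_tag in mesh.boundary:
        facets = mesh.boundary[surface_tag]
        normals = _fem.outward_normals(mesh, facets)
    elif surface_tag in mesh.surfaces:
        facets = mesh.surfaces[surface_tag]
        normals = mesh.surface_normals[surface_tag]
    else:
        raise MetricError(f"mesh has no surface tagged {surface_tag!r}")
    if flow.mu_cell is None:
        raise MetricError("flow field lacks its viscosity field")
    space = flow.space
    cells = _facet_cells(mesh, facets)

    # reference coordinates of facet midpoints inside their cells
    mids = mesh.facet_midpoints(facets)
    p0 = mesh.nodes[mesh.cells[cells, 0]]
    p1 = mesh.nodes[mesh.cells[cells, 1]]
    p2 = mesh.nodes[mesh.cells[cells, 2]]
    T = np.stack([p1 - p0, p2 - p0], axis=2)
    det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
    rhs = mids - p0
    xi = np.empty_like(rhs)
    xi[:, 0] = (T[:, 1, 1] * rhs[:, 0] - T[:, 0, 1] * rhs[:, 1]) / det
    xi[:, 1] = (-T[:, 1, 0] * rhs[:, 0] + T[:, 0, 0] * rhs[:, 1]) / det

    _, detJ, invJT = _fem._geometry_tables(space)
    tau = np.empty(len(facets))
    cvd = space.cell_vdofs()
    for i, (c, x) in enumerate(zip(cells, xi)):
        _, Gref = _fem.p2_shape(x[None, :])
        G = Gref[0] @ invJT[c].T          # (6,2) physical gradients
        grad = np.einsum("bi,bj->ij", flow.u[cvd[c]], G)
        mu = flow.mu_cell[c]
        sig = mu * (grad + grad.T)
        n = normals[i]
        trac = sig @ n
        t_t = trac - np.dot(trac, n) * n
        tau[i] = np.linalg.norm(t_t)
    areas = mesh.facet_areas(facets)
    return WSSField(facets=facets.copy(), tau=tau, areas=areas,
                    surface_tag=surface_tag, t=flow.t)


def wall_compartment_mask(mesh: Mesh, facets: np.ndarray,
                          compartment: str) -> np.ndarray:
    """Select parent-wall facets before / at / after the aneurysm neck.

    Compartment boundaries sit at the neck edges; "at" spans the neck
    footprint (the facing lower wall included), "before" is proximal and
    "after" distal of it.
    """
    x0, x1 = mesh.meta["x_neck"]
    mx = mesh.facet_midpoints(facets)[:, 0]
    if compartment == "before":
        return mx < x0
    if compartment == "at":
        return (mx >= x0) & (mx <= x1)
    if compartment == "after":
        return mx > x1
    raise MetricError(f"unknown compartment {compartment!r}")


def delta_wss(pre: WSSField, post: WSSField) -> DeltaWSSField:
    """Signed per-cell difference post - pre on the shared surface.

    Requires cell-by-cell identical discretizations; never resamples.
    """
    if pre.facets.shape != post.facets.shape or \
            not np.array_equal(np.sort(pre.facets, axis=1),
                               np.sort(post.facets, axis=1)):
        raise MetricError("pre/post surface discretizations differ; "
                          "dWSS is undefined")
    if not np.allclose(pre.areas, post.areas):
        raise MetricError("pre/post facet areas differ")
    return DeltaWSSField(facets=pre.facets.copy(),
                         dwss=post.tau - pre.tau,
                         areas=pre.areas.copy(),
                         surface_tag=pre.surface_tag, t=post.t)


def max_delta_wss(fields: Mapping[str, DeltaWSSField],
                  time_points: Sequence[str] = ("t1", "t2", "t3", "t4")
                  ) -> dict[str, float]:
    """Maximum signed dWSS over the surface, per named time point."""
    out = {}
    for tp in time_points:
        if tp not in fields:
            raise MetricError(f"missing dWSS field for time point {tp}")
        out[tp] = float(np.max(fields[tp].dwss))
    return out


def rsi(field: WSSField | DeltaWSSField) -> RSIResult:
    """Area-averaged shear: total shear force / surface area.

    Constant fields return the constant regardless of discretization.
    """
    tau = field.tau if isinstance(field, WSSField) else field.dwss
    area = float(np.sum(field.areas))
    if area <= 0:
        raise MetricError("zero total surface area")
    force = float(np.sum(tau * field.areas))
    return RSIResult(force=force, area=area, rsi=force / area, t=field.t)


def aneurysm_inflow(flow: FlowField, mesh: Mesh, rho: float,
                    surface_tag: str = "NECK") -> dict[str, float]:
    """Mass rate through the neck into the dome, in g/s.

    ``inflow`` integrates only the positive part of rho*u.n (n oriented
    into the dome); ``net`` is the signed balance.  Planar meshes give the
    rate per metre of depth.
    """
    if surface_tag not in mesh.surfaces:
        raise MetricError(f"mesh has no oriented surface {surface_tag!r}")
    facets = mesh.surfaces[surface_tag]
    normals = mesh.surface_normals[surface_tag]
    q_pos = _fem.facet_flux(flow.space, flow.u, facets, normals,
                            positive_only=True)
    q_net = _fem.facet_flux(flow.space, flow.u, facets, normals)
    return {"inflow": 1000.0 * rho * q_pos, "net": 1000.0 * rho * q_net}


def histogram_percent(field: DeltaWSSField | WSSField | np.ndarray,
                      bin_edges: Optional[np.ndarray] = None,
                      n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Percent of surface cells per shear interval.

    Returns ``(edges, percent)`` where percent sums to 100; values outside
    the given edges are collected into the two open end bins.  Default
    edges: ``n_bins`` uniform bins spanning the observed range.
    """
    if isinstance(field, (WSSField, DeltaWSSField)):
        vals = field.tau if isinstance(field, WSSField) else field.dwss
    else:
        vals = np.asarray(field, dtype=float)
    if vals.size == 0:
        raise MetricError("histogram needs at least one cell")
    if bin_edges is None:
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            hi = lo + 1.0
        bin_edges = np.linspace(lo, hi, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise MetricError("bin edges must be strictly increasing")
    clipped = np.clip(vals, bin_edges[0], np.nextafter(bin_edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=bin_edges)
    return bin_edges, 100.0 * counts / vals.size
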