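"""Idealized vessel geometries for virtual flow-diverter studies.

Generates desk-scale meshes of (a) a straight circular tube, used to verify
that a parabolic (Poiseuille) velocity profile establishes downstream of a
uniform inlet, and (b) a parent vessel with a sidewall aneurysm sac joined to
the lumen across a neck, the configuration in which a flow-diverter stent is
virtually deployed.

The stent is never inserted geometrically.  A preoperative and a stented
("postoperative") mesh for the same specification share the identical node
set and surface discretization; deployment only relabels cells of the fixed
mesh as ``STENT`` and activates the porous momentum sink there.  This makes
the per-cell difference of wall shear stress before/after deployment exact
by construction.

Two desk-scale formulations are supported: ``PLANAR_2D`` (unit-depth channel,
used for the aneurysm scenarios) and ``AXISYMMETRIC`` (r-z half plane of a
circular tube, used for profile validation).  Coordinates are metres; in
axisymmetric mode ``x`` is the axial and ``y`` the radial coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional

import numpy as np
from scipy.spatial import Delaunay


class Region(IntEnum):
    """Cell region labels."""

    LUMEN = 0
    DOME = 1
    STENT = 2


class Scenario(IntEnum):
    """Stent deployment scenarios.

    * ``NONE`` — preoperative configuration, no stent.
    * ``A`` — porous plug: a thin layer of porous medium covering the
      aneurysm neck between vessel body and dome (maximally apposed stent).
    * ``B`` — porous tube along the vessel wall spanning the neck;
      anisotropic dissipation aligned with the surface normal (small-cell
      stent).
    * ``C`` — same tube as B with isotropic dissipation (wide-mesh stent).
    """

    NONE = 0
    A = 1
    B = 2
    C = 3


#: Outer-boundary facet labels.
INLET = "INLET"
OUTLET = "OUTLET"
WALL = "WALL"
AXIS = "AXIS"
#: Interior measurement surfaces (not part of the outer boundary).
NECK = "NECK"
STENT_SURFACE = "STENT_SURFACE"

AXISYMMETRIC = "AXISYMMETRIC"
PLANAR_2D = "PLANAR_2D"


class GeometryError(ValueError):
    """Raised for invalid geometric specifications."""


@dataclass(frozen=True)
class GeometrySpec:
    """Parameters of the idealized parent-vessel + sidewall-aneurysm domain.

    All lengths in metres.  ``parent_radius`` is the half-width of the
    planar parent channel; ``dome_radius`` the radius of the circular
    aneurysm sac; ``neck_width`` the chord along which the sac opens into
    the lumen.  ``stent_thickness`` is the porous-layer thickness for
    scenarios B/C (the plug thickness of scenario A defaults to two cell
    layers and may be overridden).  ``resolution`` is the target edge
    length of the mesh.
    """

    parent_radius: float = 2.0e-3
    parent_length: float = 20.0e-3
    dome_radius: float = 3.0e-3
    neck_width: float = 2.0e-3
    stent_thickness: float = 0.8e-3
    scenario: Scenario = Scenario.NONE
    resolution: float = 0.3e-3
    #: Axial extent of the scenario-B/C tube beyond each neck edge.
    #: ``None`` means one neck width.
    stent_extent: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("parent_radius", "parent_length", "dome_radius",
                     "neck_width", "resolution"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.neck_width >= 2.0 * self.dome_radius:
            raise GeometryError(
                "neck_width must be smaller than the dome diameter "
                "(the sac must overhang its neck)")
        if self.stent_thickness <= 0:
            raise GeometryError("stent_thickness must be positive")
        if self.stent_thickness > self.parent_radius / 2.0:
            raise GeometryError(
                "stent_thickness must not exceed half the parent radius")


@dataclass
class Mesh:
    """Conforming triangle mesh with region and boundary labels.

    ``boundary`` maps outer-boundary labels (INLET/OUTLET/WALL/AXIS) to
    ``(k, 2)`` arrays of vertex-index pairs.  ``surfaces`` holds the interior
    measurement surfaces (NECK, STENT_SURFACE) in the same format together
    with per-facet unit normals in ``surface_normals`` (NECK normals point
    into the dome; STENT_SURFACE normals point from lumen into the stent).
    """

    nodes: np.ndarray
    cells: np.ndarray
    cell_region: np.ndarray
    boundary: dict[str, np.ndarray]
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)
    surface_normals: dict[str, np.ndarray] = field(default_factory=dict)
    mode: str = PLANAR_2D
    meta: dict = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------

    def cell_areas(self) -> np.ndarray:
        """Signed-positive triangle areas (m^2 in the 2-D plane)."""
        p = self.nodes[self.cells]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def cell_centroids(self) -> np.ndarray:
        return self.nodes[self.cells].mean(axis=1)

    def facet_lengths(self, facets: np.ndarray) -> np.ndarray:
        d = self.nodes[facets[:, 1]] - self.nodes[facets[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def facet_areas(self, facets: np.ndarray) -> np.ndarray:
        """Physical facet measure: length (unit depth) in planar mode,
        2*pi*r_mid*length in axisymmetric mode."""
        L = self.facet_lengths(facets)
        if self.mode == AXISYMMETRIC:
            r_mid = 0.5 * (self.nodes[facets[:, 0], 1]
                           + self.nodes[facets[:, 1], 1])
            return 2.0 * math.pi * r_mid * L
        return L

    def facet_midpoints(self, facets: np.ndarray) -> np.ndarray:
        return 0.5 * (self.nodes[facets[:, 0]] + self.nodes[facets[:, 1]])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def region_cells(self, region: Region) -> np.ndarray:
        return np.flatnonzero(self.cell_region == int(region))

    def validate(self) -> None:
        """Check the structural mesh invariants; raise GeometryError."""
        if np.any(self.cell_areas() <= 0):
            raise GeometryError("non-positive cell area (orientation broken)")
        if len(self.cell_region) != self.n_cells:
            raise GeometryError("cell_region size mismatch")
        if not np.isin(self.cell_region, [0, 1, 2]).all():
            raise GeometryError("unknown region label")
        # outer boundary facets must each bound exactly one cell; interior
        # surfaces exactly two
        counts = _edge_cell_counts(self.cells)
        for label, facets in self.boundary.items():
            for a, b in facets:
                if counts.get(_ek(a, b), 0) != 1:
                    raise GeometryError(
                        f"{label} facet ({a},{b}) is not an outer facet")
        for label, facets in self.surfaces.items():
            for a, b in facets:
                if counts.get(_ek(a, b), 0) != 2:
                    raise GeometryError(
                        f"{label} facet ({a},{b}) is not interior")
        bnd = {_ek(a, b) for f in self.boundary.values() for a, b in f}
        outer = {k for k, c in counts.items() if c == 1}
        if bnd != outer:
            raise GeometryError("boundary labels do not partition the "
                                "outer boundary")


def _ek(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


def _edge_cell_counts(cells: np.ndarray) -> dict:
    counts: dict[tuple[int, int], int] = {}
    for tri in cells:
        for i in range(3):
            k = _ek(int(tri[i]), int(tri[(i + 1) % 3]))
            counts[k] = counts.get(k, 0) + 1
    return counts


def _fix_orientation(nodes: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Flip triangles to counter-clockwise orientation."""
    p = nodes[cells]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    area2 = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    flip = area2 < 0
    cells = cells.copy()
    cells[flip] = cells[flip][:, [0, 2, 1]]
    return cells


def _grid_triangles(nx: int, ny: int) -> np.ndarray:
    """Triangulate an (nx+1)x(ny+1) structured grid with alternating
    diagonals (union-jack pattern, avoids directional bias)."""
    tris = []
    for j in range(ny):
        for i in range(nx):
            n00 = j * (nx + 1) + i
            n10 = n00 + 1
            n01 = n00 + (nx + 1)
            n11 = n01 + 1
            if (i + j) % 2 == 0:
                tris.append((n00, n10, n11))
                tris.append((n00, n11, n01))
            else:
                tris.append((n00, n10, n01))
                tris.append((n10, n11, n01))
    return np.asarray(tris, dtype=np.int64)


def make_straight_tube(radius: float, length: float, resolution: float,
                       mode: str = AXISYMMETRIC) -> Mesh:
    """Straight circular tube (axisymmetric r-z half-plane) or straight
    planar channel of half-width ``radius``.

    INLET at x=0, OUTLET at x=length, no-slip WALL on the lateral surface.
    In axisymmetric mode the symmetry axis r=0 carries the AXIS label.
    """
    if radius <= 0 or length <= 0 or resolution <= 0:
        raise GeometryError("radius, length and resolution must be positive")
    if length < 4.0 * radius:
        raise GeometryError("length must be at least two diameters")

    nx = max(4, int(round(length / resolution)))
    ny = max(4, int(round((radius if mode == AXISYMMETRIC else 2 * radius)
                          / resolution)))
    x = np.linspace(0.0, length, nx + 1)
    if mode == AXISYMMETRIC:
        y = np.linspace(0.0, radius, ny + 1)
    elif mode == PLANAR_2D:
        y = np.linspace(-radius, radius, ny + 1)
    else:
        raise GeometryError(f"unknown mode {mode!r}")
    X, Y = np.meshgrid(x, y)
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    cells = _fix_orientation(nodes, _grid_triangles(nx, ny))

    def col(i):  # node ids of grid column i (varying y)
        return np.arange(ny + 1) * (nx + 1) + i

    def row(j):  # node ids of grid row j (varying x)
        return j * (nx + 1) + np.arange(nx + 1)

    inlet = np.column_stack([col(0)[:-1], col(0)[1:]])
    outlet = np.column_stack([col(nx)[:-1], col(nx)[1:]])
    top = np.column_stack([row(ny)[:-1], row(ny)[1:]])
    bottom = np.column_stack([row(0)[:-1], row(0)[1:]])
    boundary = {INLET: inlet, OUTLET: outlet}
    if mode == AXISYMMETRIC:
        boundary[WALL] = top
        boundary[AXIS] = bottom
    else:
        boundary[WALL] = np.vstack([top, bottom])

    mesh = Mesh(nodes=nodes, cells=cells,
                cell_region=np.full(len(cells), int(Region.LUMEN),
                                    dtype=np.int64),
                boundary=boundary, mode=mode,
                meta={"kind": "tube", "radius": radius, "length": length,
                      "resolution": resolution})
    return mesh


def _neck_columns(spec: GeometrySpec) -> tuple[np.ndarray, int, int]:
    """x-coordinates of grid columns, with exact nodes at the neck edges."""
    res = spec.resolution
    xc = spec.parent_length / 2.0
    x0, x1 = xc - spec.neck_width / 2.0, xc + spec.neck_width / 2.0
    if x0 <= 0 or x1 >= spec.parent_length:
        raise GeometryError("neck does not fit inside the parent vessel")
    n_left = max(2, int(round(x0 / res)))
    n_neck = max(4, int(round(spec.neck_width / res)))
    n_right = max(2, int(round((spec.parent_length - x1) / res)))
    xs = np.concatenate([
        np.linspace(0.0, x0, n_left + 1)[:-1],
        np.linspace(x0, x1, n_neck + 1)[:-1],
        np.linspace(x1, spec.parent_length, n_right + 1),
    ])
    return xs, n_left, n_neck


def _dome_points(spec: GeometrySpec, chord_xy: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Arc boundary points and interior lattice points of the sac.

    The sac is the (convex) major circular segment above the neck chord:
    circle of radius ``dome_radius`` centred at height
    ``c = sqrt(Rd^2 - (w/2)^2)`` above the wall, cut by the wall line.
    """
    res = spec.resolution
    Rd = spec.dome_radius
    w = spec.neck_width
    H = chord_xy[0, 1]
    xc = spec.parent_length / 2.0
    c = math.sqrt(Rd * Rd - (w / 2.0) ** 2)
    O = np.array([xc, H + c])
    alpha = math.atan2(c, w / 2.0)
    sweep = math.pi + 2.0 * alpha
    n_arc = max(8, int(round(Rd * sweep / res)))
    th = (math.pi + alpha) - sweep * np.arange(1, n_arc) / n_arc
    arc = O + Rd * np.column_stack([np.cos(th), np.sin(th)])

    # hexagonal interior lattice, kept clear of the boundary
    margin = 0.55 * res
    ymin, ymax = H + margin, O[1] + Rd
    pts = []
    j = 0
    yv = ymin
    dy = res * math.sqrt(3.0) / 2.0
    while yv < ymax:
        off = 0.5 * res if j % 2 else 0.0
        xv = O[0] - Rd + off
        while xv <= O[0] + Rd:
            p = np.array([xv, yv])
            if (np.linalg.norm(p - O) <= Rd - margin) and (p[1] >= H + margin):
                pts.append(p)
            xv += res
        yv += dy
        j += 1
    interior = (np.array(pts) if pts else np.empty((0, 2)))
    return arc, interior


def make_sidewall_aneurysm(spec: GeometrySpec) -> Mesh:
    """Parent vessel with a sidewall aneurysm sac; optional stent region.

    The parent vessel is a planar channel of width ``2*parent_radius``; the
    sac is a circular segment attached to the upper wall across the NECK
    chord.  The preoperative (``scenario=NONE``) and stented meshes for one
    spec are node-identical; see :func:`embed_stent_region`.
    """
    xs, n_left, n_neck = _neck_columns(spec)
    H = 2.0 * spec.parent_radius
    ny = max(4, int(round(H / spec.resolution)))
    ys = np.linspace(0.0, H, ny + 1)
    nx = len(xs) - 1
    X, Y = np.meshgrid(xs, ys)
    ch_nodes = np.column_stack([X.ravel(), Y.ravel()])
    ch_cells = _grid_triangles(nx, ny)

    top_row = ny * (nx + 1) + np.arange(nx + 1)
    neck_slice = top_row[n_left:n_left + n_neck + 1]
    chord_xy = ch_nodes[neck_slice]

    arc, interior = _dome_points(spec, chord_xy)
    dome_local = np.vstack([chord_xy, arc, interior])
    tri = Delaunay(dome_local)
    dcells = tri.simplices
    # drop degenerate slivers from collinear chord points
    p = dome_local[dcells]
    a2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
          - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    dcells = dcells[np.abs(a2) > 1e-9 * spec.resolution ** 2]

    # map dome-local node ids to global: chord nodes reuse channel ids
    n_ch = len(ch_nodes)
    n_chord = len(chord_xy)
    g = np.empty(len(dome_local), dtype=np.int64)
    g[:n_chord] = neck_slice
    g[n_chord:] = n_ch + np.arange(len(dome_local) - n_chord)
    nodes = np.vstack([ch_nodes, dome_local[n_chord:]])
    dome_cells = g[dcells]

    cells = np.vstack([ch_cells, dome_cells])
    cells = _fix_orientation(nodes, cells)
    region = np.concatenate([
        np.full(len(ch_cells), int(Region.LUMEN), dtype=np.int64),
        np.full(len(dome_cells), int(Region.DOME), dtype=np.int64),
    ])

    def col(i):
        return np.arange(ny + 1) * (nx + 1) + i

    bottom = np.column_stack([np.arange(nx), np.arange(1, nx + 1)])
    top_facets = np.column_stack([top_row[:-1], top_row[1:]])
    is_neck = np.zeros(nx, dtype=bool)
    is_neck[n_left:n_left + n_neck] = True
    wall_top = top_facets[~is_neck]
    neck_facets = top_facets[is_neck]
    # dome outer arc: boundary edges of the dome triangulation except chord
    arc_ids = n_ch + np.arange(len(arc))
    arc_chain = np.concatenate([[neck_slice[0]], arc_ids, [neck_slice[-1]]])
    dome_wall = np.column_stack([arc_chain[:-1], arc_chain[1:]])

    boundary = {
        INLET: np.column_stack([col(0)[:-1], col(0)[1:]]),
        OUTLET: np.column_stack([col(nx)[:-1], col(nx)[1:]]),
        WALL: np.vstack([bottom, wall_top, dome_wall]),
    }
    surfaces = {NECK: neck_facets}
    surface_normals = {NECK: np.tile([0.0, 1.0], (len(neck_facets), 1))}

    mesh = Mesh(nodes=nodes, cells=cells, cell_region=region,
                boundary=boundary, surfaces=surfaces,
                surface_normals=surface_normals, mode=PLANAR_2D,
                meta={"kind": "sidewall_aneurysm",
                      "H": H, "xc": spec.parent_length / 2.0,
                      "neck_width": spec.neck_width,
                      "x_neck": (float(chord_xy[0, 0]),
                                 float(chord_xy[-1, 0])),
                      "resolution": spec.resolution,
                      "spec": spec})
    if spec.scenario != Scenario.NONE:
        mesh = embed_stent_region(mesh, spec.scenario, spec.stent_thickness,
                                  extent=spec.stent_extent)
    return mesh


def embed_stent_region(mesh: Mesh, scenario: Scenario,
                       thickness: Optional[float] = None,
                       extent: Optional[float] = None) -> Mesh:
    """Deploy the virtual stent by relabelling cells of a fixed mesh.

    Scenario A marks a thin layer of DOME cells covering the neck (plug);
    scenarios B/C mark a wall-adjacent layer of LUMEN cells of the given
    ``thickness`` spanning the neck plus ``extent`` on each side (default one
    neck width).  Node coordinates and every facet are untouched, so wall
    shear stresses before and after deployment live on identical surface
    cells.  STENT_SURFACE facets are the luminal face of the stent layer
    (facets separating STENT from LUMEN cells; for scenario A this is the
    neck itself).
    """
    if scenario == Scenario.NONE:
        return mesh
    if mesh.meta.get("kind") != "sidewall_aneurysm":
        raise GeometryError("stent embedding requires a sidewall-aneurysm "
                            "mesh with a NECK surface")
    if NECK not in mesh.surfaces:
        raise GeometryError("mesh lacks a NECK surface")
    res = mesh.meta["resolution"]
    H = mesh.meta["H"]
    x0, x1 = mesh.meta["x_neck"]
    if thickness is None:
        thickness = 2.0 * res if scenario == Scenario.A else None
    if thickness is None or thickness <= 0:
        raise GeometryError("stent thickness must be positive")
    if scenario in (Scenario.B, Scenario.C) and thickness > H / 2.0:
        raise GeometryError("stent thickness exceeds the lumen radius")

    region = mesh.cell_region.copy()
    cen = mesh.cell_centroids()
    if scenario == Scenario.A:
        mask = (region == int(Region.DOME)) & (cen[:, 1] <= H + thickness)
        # keep the plug to the neck footprint (clip overhang cells)
        mask &= (cen[:, 0] >= x0 - 0.5 * res) & (cen[:, 0] <= x1 + 0.5 * res)
    else:
        ext = (x1 - x0) if extent is None else extent
        mask = ((region == int(Region.LUMEN))
                & (cen[:, 1] >= H - thickness)
                & (cen[:, 0] >= x0 - ext) & (cen[:, 0] <= x1 + ext))
    if not mask.any():
        raise GeometryError("stent region is empty; refine the mesh or "
                            "increase the thickness")
    region[mask] = int(Region.STENT)

    # luminal face: facets between STENT and LUMEN cells
    edge_cells: dict[tuple[int, int], list[int]] = {}
    for ci, tri in enumerate(mesh.cells):
        for i in range(3):
            k = _ek(int(tri[i]), int(tri[(i + 1) % 3]))
            edge_cells.setdefault(k, []).append(ci)
    sfacets, snormals = [], []
    for k, cs in edge_cells.items():
        if len(cs) != 2:
            continue
        r0, r1 = region[cs[0]], region[cs[1]]
        if {int(r0), int(r1)} == {int(Region.STENT), int(Region.LUMEN)}:
            lum = cs[0] if r0 == int(Region.LUMEN) else cs[1]
            a, b = k
            t = mesh.nodes[b] - mesh.nodes[a]
            n = np.array([t[1], -t[0]])
            n /= np.linalg.norm(n)
            mid = 0.5 * (mesh.nodes[a] + mesh.nodes[b])
            if np.dot(n, mid - cen[lum]) < 0:
                n = -n  # orient from lumen into the stent
            sfacets.append(k)
            snormals.append(n)
    order = np.lexsort((np.array([f[1] for f in sfacets]),
                        np.array([f[0] for f in sfacets])))
    sfacets = np.asarray(sfacets, dtype=np.int64)[order]
    snormals = np.asarray(snormals)[order]

    surfaces = dict(mesh.surfaces)
    surface_normals = dict(mesh.surface_normals)
    surfaces[STENT_SURFACE] = sfacets
    surface_normals[STENT_SURFACE] = snormals
    meta = dict(mesh.meta)
    meta["scenario"] = Scenario(scenario).name
    meta["stent_thickness"] = thickness
    return replace(mesh, cell_region=region, surfaces=surfaces,
                   surface_normals=surface_normals, meta=meta)
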