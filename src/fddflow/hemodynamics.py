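"""Steady and pulsatile incompressible-flow solver.

Discretization is Taylor-Hood (P2 velocity / P1 pressure) finite elements
with Picard linearization of the convective term.  The momentum equation
carries the variable (mixed Newtonian/Casson) viscosity and the porous
momentum sink of the stent region; continuity is enforced pointwise in the
weak sense, which makes the discrete inflow/outflow balance exact up to
linear-solver roundoff.

Boundary conditions follow the clinical-simulation setting this package
emulates: a uniform (plug) velocity at the inlet, no-slip walls, and
"opening" outlets modelled as zero normal traction with the sign of the
normal velocity unconstrained, so vortices near the outlet may draw fluid
back into the domain without aborting the solve.

The pulsatile solver integrates three repeats of a 1 s cardiac cycle with
backward-Euler steps of dt = 0.01 s (300 steps); transients die out during
the first seconds and analysis is restricted to the final second, where the
named cycle points t1 = 2.03 s (late diastole), t2 = 2.25 s and
t3 = 2.36 s (systolic peak plateau) and t4 = 2.70 s (diastole) live.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from . import _fem
from .geometry import AXIS, AXISYMMETRIC, INLET, Mesh, Region, WALL
from .porous import PorousSpec, dissipation_tensor
from .rheology import RheologyParams, assign_viscosity, strain_rate_invariant

#: Named cardiac-cycle sample times (s) within the 3 s simulation window.
TIME_POINTS = {"t1": 2.03, "t2": 2.25, "t3": 2.36, "t4": 2.70}


class SolverError(RuntimeError):
    """Nonlinear iteration failed to converge; carries the residual
    history."""

    def __init__(self, msg: str, history: Sequence[float] = (),
                 step: Optional[int] = None):
        super().__init__(msg)
        self.history = list(history)
        self.step = step


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls of the flow solver.

    Steady solves iterate Picard updates until the relative velocity
    increment falls below ``steady_tol``; pulsatile steps use backward
    Euler with per-step Picard tolerance ``step_tol``.
    """

    dt: float = 0.01
    period: float = 3.0
    steady_tol: float = 1.0e-8
    step_tol: float = 1.0e-5
    max_picard: int = 60
    max_picard_step: int = 25
    picard_before_newton: int = 3
    relaxation: float = 1.0
    strain_convention: str = "plain"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.period <= 0:
            raise ValueError("dt and period must be positive")
        if self.steady_tol <= 0 or self.step_tol <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.period / self.dt))


@dataclass
class Waveform:
    """Periodic inlet waveform: sample times (s) and mean velocities (m/s).

    Lookup is periodic with linear interpolation between samples.
    """

    times: np.ndarray
    velocities: np.ndarray
    period: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.velocities.shape:
            raise ValueError("times and velocities must be equal-length 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.velocities < 0):
            raise ValueError("inlet velocities must be non-negative")
        if self.period <= 0:
            raise ValueError("period must be positive")

    def __call__(self, t) -> np.ndarray | float:
        tau = np.mod(np.asarray(t, dtype=float) - self.times[0], self.period)
        ts = self.times - self.times[0]
        tp = np.concatenate([ts, [self.period]])
        vp = np.concatenate([self.velocities, [self.velocities[0]]])
        out = np.interp(tau, tp, vp)
        return float(out) if np.isscalar(t) else out


def inlet_velocity(waveform: Waveform, t: float) -> float:
    """Uniform (plug) inlet speed at time t: periodic linear lookup."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return float(waveform(t))


def scale_waveform(reference: Waveform, factor: float) -> Waveform:
    """Scale every velocity sample by ``factor`` (period unchanged)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return Waveform(times=reference.times.copy(),
                    velocities=reference.velocities * factor,
                    period=reference.period)


#: Inlet speeds (m/s) at the named cycle points for the reference
#: internal-carotid waveform.
REFERENCE_ANCHORS = {"t1": 0.057, "t2": 0.071, "t3": 0.071, "t4": 0.06}


def build_reference_waveform(anchors: Optional[dict] = None,
                             n_samples: int = 100) -> Waveform:
    """Smooth 1 s two-phase cardiac-like waveform through the four anchor
    speeds at t1..t4.

    A periodic cubic spline is drawn through the anchor points (mapped to
    cycle phase) and densely sampled; the anchor phases are kept on the
    sample grid so the anchor values are reproduced exactly.
    """
    anchors = dict(REFERENCE_ANCHORS if anchors is None else anchors)
    missing = set(TIME_POINTS) - set(anchors)
    if missing:
        raise ValueError(f"missing anchor values for {sorted(missing)}")
    if any(v < 0 for v in anchors.values()):
        raise ValueError("anchor velocities must be non-negative")
    phases = np.array([TIME_POINTS[k] % 1.0 for k in ("t1", "t2", "t3", "t4")])
    vals = np.array([anchors[k] for k in ("t1", "t2", "t3", "t4")])
    order = np.argsort(phases)
    ph, va = phases[order], vals[order]
    spl = CubicSpline(np.concatenate([ph, [ph[0] + 1.0]]),
                      np.concatenate([va, [va[0]]]), bc_type="periodic")
    ts = np.round(np.linspace(0.0, 1.0, n_samples + 1)[:-1], 12)
    vs = np.maximum(spl(ts), 0.0)
    return Waveform(times=ts, velocities=vs, period=1.0)


@dataclass
class FlowField:
    """Velocity/pressure snapshot on a mesh at one time instant.

    ``u`` lives on the P2 velocity nodes (vertices then edge midpoints),
    ``p`` on the vertices.  ``mu_cell`` is the per-cell viscosity the
    momentum equation was closed with (needed for shear-stress extraction).
    """

    mesh: Mesh
    u: np.ndarray
    p: np.ndarray
    t: float = 0.0
    mu_cell: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)
    _space: Optional[_fem.FEMSpace] = field(default=None, repr=False)

    @property
    def space(self) -> _fem.FEMSpace:
        if self._space is None:
            self._space = _fem.build_space(self.mesh)
        return self._space

    def sample_velocity(self, pts: np.ndarray) -> np.ndarray:
        return _fem.sample_velocity(self.space, self.u, np.atleast_2d(pts))

    def sample_pressure(self, pts: np.ndarray) -> np.ndarray:
        loc = _fem.PointLocator(self.mesh)
        cells, refs = loc.locate(np.atleast_2d(pts))
        N = _fem.p1_shape(refs)
        return np.einsum("kb,kb->k", N, self.p[self.mesh.cells[cells]])

    def cell_gradients(self) -> np.ndarray:
        return _fem.cell_velocity_gradients(self.space, self.u)

    def boundary_flux(self, label: str, positive_only: bool = False) -> float:
        """Outward volumetric flux through a labelled outer boundary."""
        facets = self.mesh.boundary[label]
        normals = _fem.outward_normals(self.mesh, facets)
        return _fem.facet_flux(self.space, self.u, facets, normals,
                               positive_only=positive_only)


@dataclass
class FlowSeries:
    """Stored time steps of a pulsatile run."""

    fields: list
    config: SolverConfig

    def at_time(self, t: float, tol: float = 1e-9) -> FlowField:
        for f in self.fields:
            if abs(f.t - t) < tol:
                return f
        raise KeyError(f"no stored step at t={t}")

    def at_named(self, name: str) -> FlowField:
        return self.at_time(TIME_POINTS[name])

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.fields])


def _dirichlet(space: _fem.FEMSpace, mesh: Mesh, u_in: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet velocity dofs: plug inlet (+x), no-slip walls, axis
    symmetry.  Wall values win at shared corner nodes."""
    nv = space.n_vnodes
    vals: dict[int, float] = {}

    def set_node(n, ux=None, uy=None):
        if ux is not None:
            vals[n] = ux
        if uy is not None:
            vals[nv + n] = uy

    for a in (INLET,):
        if a in mesh.boundary:
            for n in np.unique(space.facet_vnodes(mesh.boundary[a])):
                set_node(int(n), ux=u_in, uy=0.0)
    if AXIS in mesh.boundary:
        for n in np.unique(space.facet_vnodes(mesh.boundary[AXIS])):
            set_node(int(n), uy=0.0)
    if WALL in mesh.boundary:
        for n in np.unique(space.facet_vnodes(mesh.boundary[WALL])):
            set_node(int(n), ux=0.0, uy=0.0)
    dofs = np.fromiter(vals.keys(), dtype=np.int64)
    vv = np.fromiter(vals.values(), dtype=float)
    order = np.argsort(dofs)
    return dofs[order], vv[order]


def _cell_viscosity(space, mesh, u, rheology, convention):
    grads = _fem.cell_velocity_gradients(space, u)
    gd = strain_rate_invariant(grads, convention=convention)
    return assign_viscosity(mesh, gd, rheology)


def _divergence_residual(space, u) -> float:
    """L2 norm of the cell-centre divergence (u_r/r included in
    axisymmetric mode), normalized by the L2 norm of the velocity
    gradient (0 for an exactly solenoidal field)."""
    mesh = space.mesh
    g = _fem.cell_velocity_gradients(space, u)
    div = g[:, 0, 0] + g[:, 1, 1]
    if mesh.mode == AXISYMMETRIC:
        N, _ = _fem.p2_shape(np.array([[1 / 3, 1 / 3]]))
        uc = np.einsum("b,cbd->cd", N[0], u[space.cell_vdofs()])
        r = mesh.cell_centroids()[:, 1]
        div = div + uc[:, 1] / np.maximum(r, 1e-300)
    scale = np.sqrt(np.mean(g ** 2).sum()) + 1e-300
    return float(np.sqrt(np.mean(div ** 2)) / scale)


def solve_steady(mesh: Mesh, rheology: RheologyParams,
                 porous: Optional[PorousSpec] = None,
                 inlet_speed: float = 0.06,
                 config: Optional[SolverConfig] = None,
                 space: Optional[_fem.FEMSpace] = None) -> FlowField:
    """Converged steady flow with mixed rheology and optional stent sink.

    Raises :class:`SolverError` with the increment history if the Picard
    iteration does not converge within its budget.
    """
    if inlet_speed <= 0:
        raise ValueError("inlet speed must be positive")
    config = config or SolverConfig()
    space = space or _fem.build_space(mesh)
    D_cell = None
    if porous is not None and len(mesh.region_cells(Region.STENT)):
        D_cell = dissipation_tensor(mesh, porous)
    dofs, vals = _dirichlet(space, mesh, inlet_speed)

    nv = space.n_vnodes
    u = np.zeros((nv, 2))
    history: list[float] = []
    mu_cell = None
    p = None
    r_prev = None
    omega = config.relaxation
    for it in range(config.max_picard):
        mu_cell = _cell_viscosity(space, mesh, u, rheology,
                                  config.strain_convention)
        adv = u if it > 0 or np.any(u) else None
        # a few Picard sweeps for robustness, then Newton for speed
        newton = it >= config.picard_before_newton and adv is not None
        A, rhs = _fem.assemble(space, mu_cell, rheology.rho, adv=adv,
                               D_cell=D_cell, newton=newton)
        A, rhs = _fem.apply_dirichlet(A, rhs, dofs, vals)
        x = _fem.solve_linear(A, rhs)
        u_new = np.column_stack([x[:nv], x[nv:2 * nv]])
        p = x[2 * nv:]
        scale = max(np.abs(u_new).max(), 1e-300)
        r = u_new - u
        err = np.abs(r).max() / scale
        history.append(err)
        if err < config.steady_tol:
            u = u_new
            break
        # Aitken relaxation: accelerates the linearly convergent
        # viscosity/advection fixed point (dominant in the Casson dome)
        if r_prev is not None:
            dr = r - r_prev
            denom = float(np.sum(dr * dr))
            if denom > 0:
                omega = float(np.clip(
                    -omega * np.sum(r_prev * dr) / denom, 0.1, 20.0))
        u = u + omega * r
        r_prev = r
    else:
        raise SolverError(
            f"steady Picard iteration did not reach {config.steady_tol:g} "
            f"in {config.max_picard} iterations", history)
    return FlowField(mesh=mesh, u=u, p=p, t=0.0, mu_cell=mu_cell,
                     diagnostics={"picard_history": history,
                                  "div_residual": _divergence_residual(space, u)},
                     _space=space)


def solve_pulsatile(mesh: Mesh, rheology: RheologyParams,
                    porous: Optional[PorousSpec],
                    waveform: Waveform,
                    config: Optional[SolverConfig] = None,
                    store_from: float = 0.0,
                    space: Optional[_fem.FEMSpace] = None) -> FlowSeries:
    """Backward-Euler pulsatile run over ``config.period`` (default 3 s).

    Snapshots with t >= ``store_from`` are stored (pass 2.0 to keep only
    the final cycle).  Raises :class:`SolverError` with the failing step
    index if a step's Picard iteration diverges.
    """
    config = config or SolverConfig()
    space = space or _fem.build_space(mesh)
    D_cell = None
    if porous is not None and len(mesh.region_cells(Region.STENT)):
        D_cell = dissipation_tensor(mesh, porous)
    nv = space.n_vnodes

    # start from the steady solution at the cycle-start inlet speed: the
    # flow is then near-periodic well before the analysed final second
    u0 = float(waveform(0.0))
    if u0 <= 0:
        u0 = max(float(np.mean(waveform.velocities)), 1e-6)
    init = solve_steady(mesh, rheology, porous, inlet_speed=u0,
                        config=config, space=space)
    u = init.u.copy()

    fields: list[FlowField] = []
    for n in range(1, config.n_steps + 1):
        t = n * config.dt
        dofs, vals = _dirichlet(space, mesh, inlet_velocity(waveform, t))
        u_old = u.copy()
        u_it = u
        mu_cell = None
        converged = False
        for k in range(config.max_picard_step):
            mu_cell = _cell_viscosity(space, mesh, u_it, rheology,
                                      config.strain_convention)
            A, rhs = _fem.assemble(space, mu_cell, rheology.rho, adv=u_it,
                                   D_cell=D_cell, dt=config.dt, u_old=u_old)
            A, rhs = _fem.apply_dirichlet(A, rhs, dofs, vals)
            x = _fem.solve_linear(A, rhs)
            u_new = np.column_stack([x[:nv], x[nv:2 * nv]])
            p = x[2 * nv:]
            err = np.abs(u_new - u_it).max() / max(np.abs(u_new).max(), 1e-300)
            u_it = u_new
            if err < config.step_tol:
                converged = True
                break
        if not converged or not np.isfinite(u_it).all():
            raise SolverError(f"pulsatile step {n} (t={t:.2f} s) did not "
                              "converge", step=n)
        u = u_it
        if t >= store_from - 1e-12:
            fields.append(FlowField(
                mesh=mesh, u=u.copy(), p=p.copy(), t=round(t, 10),
                mu_cell=mu_cell.copy(),
                diagnostics={"picard_iters": k + 1},
                _space=space))
    return FlowSeries(fields=fields, config=config)


def viscous_dissipation(flow: FlowField,
                        D_cell: Optional[np.ndarray] = None) -> float:
    """Domain-integrated dissipation: 2*mu*eps:eps, plus the porous sink
    power u.(D mu u) when the dissipation tensor field is given
    (W per metre of depth in planar mode; one-point cell quadrature)."""
    space = flow.space
    mesh = flow.mesh
    g = flow.cell_gradients()
    eps = 0.5 * (g + np.swapaxes(g, 1, 2))
    areas = mesh.cell_areas()
    if mesh.mode == AXISYMMETRIC:
        areas = areas * 2.0 * np.pi * mesh.cell_centroids()[:, 1]
    mu = flow.mu_cell
    total = float(np.sum(2.0 * mu * np.einsum("kij,kij->k", eps, eps)
                         * areas))
    if D_cell is not None:
        N, _ = _fem.p2_shape(np.array([[1 / 3, 1 / 3]]))
        uc = np.einsum("b,cbd->cd", N[0], flow.u[space.cell_vdofs()])
        total += float(np.sum(
            mu * np.einsum("ki,kij,kj->k", uc, D_cell, uc) * areas))
    return total
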