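"""Porous-medium representation of the deployed flow-diverter.

The stented volume acts on the flow through a Brinkman-type momentum sink

    F_i = -( sum_j D_ij * mu * u_j  +  sum_j C_ij * rho/2 * |u| * u_j )

per unit volume, where ``D`` (1/m^2) is the dissipation tensor and the
convective (Forchheimer) tensor ``C`` is identically zero: in the stent
region velocities are small and the quadratic term is negligible.  ``D`` is
isotropic (``d * I``) for the neck-plug scenario A and the wide-mesh tube
scenario C, and normal-aligned (``d * n (x) n``, damping only the velocity
component crossing the stent surface) for the small-cell tube scenario B.

The default magnitude ``d`` is calibrated once on the reference idealized
geometry so that the scenario-A plug reduces steady inflow through the
aneurysm neck by roughly one fifth, matching the directionality and scale
of the clinical-geometry computations this model emulates.  The literal
"unit tensor" value 1 m^-2 remains selectable but is a physically
negligible sink at SI scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Mesh, Region, Scenario, STENT_SURFACE

ISOTROPIC = "ISOTROPIC"
NORMAL_ALIGNED = "NORMAL_ALIGNED"

#: Calibrated default dissipation magnitude (1/m^2); see module docstring.
DEFAULT_D_MAGNITUDE = 9.0e7


class PorousConfigError(ValueError):
    """Raised for invalid porous-model configuration."""


def direction_mode_for(scenario: Scenario) -> str:
    """Tensor structure assigned to each deployment scenario."""
    return NORMAL_ALIGNED if scenario == Scenario.B else ISOTROPIC


@dataclass(frozen=True)
class PorousSpec:
    """Dissipation model of one stent scenario.

    ``C`` is stored for completeness but is identically zero and cannot be
    enabled.
    """

    scenario: Scenario = Scenario.A
    d_magnitude: float = DEFAULT_D_MAGNITUDE
    direction_mode: str | None = None
    C: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        if self.scenario == Scenario.NONE:
            raise PorousConfigError("porous model needs a stent scenario")
        if self.d_magnitude <= 0:
            raise PorousConfigError("d_magnitude must be positive")
        if self.C != 0.0:
            raise PorousConfigError("the convective tensor C is fixed at 0")
        mode = self.direction_mode
        if mode is None:
            object.__setattr__(self, "direction_mode",
                               direction_mode_for(self.scenario))
        elif mode not in (ISOTROPIC, NORMAL_ALIGNED):
            raise PorousConfigError(f"unknown direction mode {mode!r}")
        else:
            expected = direction_mode_for(self.scenario)
            if mode != expected:
                raise PorousConfigError(
                    f"scenario {self.scenario.name} uses {expected}")


def dissipation_tensor(mesh: Mesh, spec: PorousSpec) -> np.ndarray:
    """Per-cell 2x2 dissipation tensor field D (1/m^2).

    Zero outside STENT cells.  In NORMAL_ALIGNED mode each STENT cell gets
    ``d * n (x) n`` with ``n`` the unit normal of the nearest stent-surface
    facet (ties resolved to the smallest facet index, deterministically).
    """
    stent = mesh.region_cells(Region.STENT)
    if len(stent) == 0:
        raise PorousConfigError("mesh has no STENT cells")
    D = np.zeros((mesh.n_cells, 2, 2))
    if spec.direction_mode == ISOTROPIC:
        D[stent] = spec.d_magnitude * np.eye(2)
        return D
    facets = mesh.surfaces.get(STENT_SURFACE)
    normals = mesh.surface_normals.get(STENT_SURFACE)
    if facets is None or normals is None or len(facets) == 0:
        raise PorousConfigError(
            "NORMAL_ALIGNED mode needs STENT_SURFACE facets with normals")
    mids = mesh.facet_midpoints(facets)
    cen = mesh.cell_centroids()[stent]
    # cKDTree returns the smallest index among exact ties
    _, nearest = cKDTree(mids).query(cen)
    n = normals[nearest]
    D[stent] = spec.d_magnitude * np.einsum("ki,kj->kij", n, n)
    return D


def porous_body_force(D: np.ndarray, mu: np.ndarray,
                      u: np.ndarray) -> np.ndarray:
    """Momentum sink F_i = -sum_j D_ij * mu * u_j per cell (N/m^3).

    The quadratic convective contribution is identically zero.  F.u <= 0
    always: the term can only dissipate kinetic energy.
    """
    D = np.asarray(D, dtype=float)
    u = np.asarray(u, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return -np.einsum("kij,k,kj->ki", D, mu, u)
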