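"""Blood rheology: Casson shear-thinning law and the strain-rate invariant.

The flow solver runs a *mixed* viscosity setting: Newtonian blood
(``mu0``) in the parent lumen and stent region, and the Casson effective
viscosity in the aneurysm dome after stenting, where shear rates are low
and shear-thinning matters physiologically.  The Casson law used is

    mu(gamma_dot) = (sqrt(tau0 / gamma_dot) + sqrt(mu0))^2

with the yield parameter ``tau0`` and the Newtonian plateau ``mu0`` both
0.04 dyne*s/cm^2 in CGS (0.004 Pa*s in SI).  The law is singular at zero
shear rate, so ``gamma_dot`` is floored at ``gamma_floor`` before
evaluation; the resulting viscosity is finite and bounded below by ``mu0``.

The scalar shear rate is the second invariant of the strain-rate tensor
eps_ij = (du_i/dx_j + du_j/dx_i)/2 in the plain double-contraction form

    gamma_dot = sqrt(sum_ij eps_ij * eps_ij)

(no factor-2 convention; the common sqrt(2 eps:eps) variant is available
via ``convention="doubled"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Mesh, Region

#: CGS dyne*s/cm^2 -> SI Pa*s
CGS_VISCOSITY_TO_SI = 0.1


@dataclass(frozen=True)
class RheologyParams:
    """Casson constants and fluid density (SI units).

    tau0 : Casson yield parameter, Pa*s (0.004 Pa*s = 0.04 dyne*s/cm^2)
    mu0 : Newtonian viscosity, Pa*s
    rho : density, kg/m^3
    gamma_floor : strain-rate regularization floor, 1/s
    """

    tau0: float = 0.004
    mu0: float = 0.004
    rho: float = 997.0
    gamma_floor: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.tau0 < 0:
            raise ValueError("tau0 must be non-negative")
        if self.mu0 <= 0 or self.rho <= 0 or self.gamma_floor <= 0:
            raise ValueError("mu0, rho and gamma_floor must be positive")

    @classmethod
    def from_cgs(cls, tau0: float = 0.04, mu0: float = 0.04,
                 rho: float = 997.0, gamma_floor: float = 1.0e-3
                 ) -> "RheologyParams":
        """Build from viscosity constants given in dyne*s/cm^2."""
        return cls(tau0=tau0 * CGS_VISCOSITY_TO_SI,
                   mu0=mu0 * CGS_VISCOSITY_TO_SI,
                   rho=rho, gamma_floor=gamma_floor)


def strain_rate_invariant(velocity_gradient: np.ndarray,
                          convention: str = "plain") -> np.ndarray:
    """Scalar shear rate from the velocity-gradient tensor(s).

    Parameters
    ----------
    velocity_gradient
        Array of shape ``(..., d, d)`` with entries ``du_i/dx_j``.
    convention
        ``"plain"`` (default): ``sqrt(eps:eps)``; ``"doubled"``:
        ``sqrt(2 eps:eps)``.
    """
    g = np.asarray(velocity_gradient, dtype=float)
    if g.shape[-1] != g.shape[-2]:
        raise ValueError("velocity gradient must be square in its last axes")
    eps = 0.5 * (g + np.swapaxes(g, -1, -2))
    s = np.einsum("...ij,...ij->...", eps, eps)
    if convention == "doubled":
        s = 2.0 * s
    elif convention != "plain":
        raise ValueError(f"unknown convention {convention!r}")
    return np.sqrt(s)


def casson_viscosity(gamma_dot, params: RheologyParams):
    """Casson effective viscosity; regularized at ``params.gamma_floor``.

    Strictly decreasing in the shear rate, tends to ``mu0`` as
    gamma_dot -> infinity, and never falls below ``mu0``.
    """
    gd = np.maximum(np.asarray(gamma_dot, dtype=float), params.gamma_floor)
    return (np.sqrt(params.tau0 / gd) + np.sqrt(params.mu0)) ** 2


def assign_viscosity(mesh: Mesh, gamma_dot_cells: np.ndarray,
                     params: RheologyParams,
                     convention: str = "plain") -> np.ndarray:
    """Per-cell dynamic viscosity for the mixed Newtonian/Casson setting.

    DOME cells get the Casson viscosity from their local shear rate; LUMEN
    and STENT cells get the Newtonian ``mu0``.
    """
    del convention  # the invariant convention is applied upstream
    if mesh.cell_region is None or len(mesh.cell_region) != mesh.n_cells:
        raise ValueError("mesh is missing region labels")
    gd = np.asarray(gamma_dot_cells, dtype=float)
    if gd.shape != (mesh.n_cells,):
        raise ValueError("gamma_dot_cells must be a per-cell array")
    mu = np.full(mesh.n_cells, params.mu0)
    dome = mesh.cell_region == int(Region.DOME)
    mu[dome] = casson_viscosity(gd[dome], params)
    return mu
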