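"""Shared fixtures: coarse but converged solves, reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from fddflow.geometry import (GeometrySpec, Scenario, embed_stent_region,
                              make_sidewall_aneurysm, make_straight_tube)
from fddflow.hemodynamics import solve_steady
from fddflow.porous import PorousSpec
from fddflow.rheology import RheologyParams

TUBE_RADIUS = 0.002
TUBE_LENGTH = 0.02
TUBE_RES = 0.00025


@pytest.fixture(scope="session")
def rheo():
    return RheologyParams()


@pytest.fixture(scope="session")
def tube_mesh():
    return make_straight_tube(TUBE_RADIUS, TUBE_LENGTH, TUBE_RES)


@pytest.fixture(scope="session")
def tube_flow(tube_mesh, rheo):
    """Axisymmetric tube solve at the reference inlet speed (Re ~ 60)."""
    return solve_steady(tube_mesh, rheo, inlet_speed=0.06)


@pytest.fixture(scope="session")
def tube_flow_lowre(tube_mesh, rheo):
    """Low-Reynolds tube solve: fully developed well before the outlet,
    the regime where the analytic Poiseuille formulas apply pointwise."""
    return solve_steady(tube_mesh, rheo, inlet_speed=0.01)


ANEURYSM_SPEC = GeometrySpec(resolution=0.4e-3)


@pytest.fixture(scope="session")
def aneurysm_pre():
    return make_sidewall_aneurysm(ANEURYSM_SPEC)


@pytest.fixture(scope="session")
def aneurysm_stented(aneurysm_pre):
    return embed_stent_region(aneurysm_pre, Scenario.A)


@pytest.fixture(scope="session")
def aneurysm_flow_pre(aneurysm_pre, rheo):
    return solve_steady(aneurysm_pre, rheo, inlet_speed=0.06)


@pytest.fixture(scope="session")
def aneurysm_flow_stented(aneurysm_stented, rheo):
    return solve_steady(aneurysm_stented, rheo,
                        porous=PorousSpec(scenario=Scenario.A),
                        inlet_speed=0.06)


def mean_inlet_speed(flow) -> float:
    """Bulk velocity from the measured inlet flux (plug corner nodes are
    clipped by the no-slip wall, so the realized flux sets the mean)."""
    mesh = flow.mesh
    area = abs(np.pi * TUBE_RADIUS ** 2)
    return -flow.boundary_flux("INLET") / area
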