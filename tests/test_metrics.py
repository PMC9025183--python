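"""WSS extraction, dWSS differencing, RSI, neck inflow, histograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fddflow.geometry import NECK, STENT_SURFACE, WALL
from fddflow.hemodynamics import FlowField
from fddflow.metrics import (DeltaWSSField, MetricError, WSSField,
                             aneurysm_inflow, delta_wss, histogram_percent,
                             max_delta_wss, rsi, wall_compartment_mask,
                             wall_shear_stress)
from fddflow.stats import PoiseuilleSpec, poiseuille_profile

from conftest import TUBE_LENGTH, TUBE_RADIUS, mean_inlet_speed


def _const_wss(tau_vals, areas, tag="WALL", t=0.0):
    n = len(tau_vals)
    facets = np.column_stack([np.arange(n), np.arange(1, n + 1)])
    return WSSField(facets=facets, tau=np.asarray(tau_vals, dtype=float),
                    areas=np.asarray(areas, dtype=float), surface_tag=tag,
                    t=t)


class TestWallShearStress:
    def test_quiescent_flow_zero_wss(self, tube_mesh, rheo):
        flow = FlowField(mesh=tube_mesh, u=np.zeros((0, 2)),
                         p=np.zeros(tube_mesh.n_nodes))
        flow.u = np.zeros((flow.space.n_vnodes, 2))
        flow.mu_cell = np.full(tube_mesh.n_cells, rheo.mu0)
        wss = wall_shear_stress(flow, tube_mesh, WALL)
        assert np.allclose(wss.tau, 0.0)

    def test_poiseuille_wall_shear_matches_pressure_drop(self,
                                                         tube_flow_lowre):
        """Developed tube flow: tau_w = dP * R / (2 dL) on any developed
        segment."""
        flow = tube_flow_lowre
        mesh = flow.mesh
        z0, z1 = 0.4 * TUBE_LENGTH, 0.9 * TUBE_LENGTH
        p0 = flow.sample_pressure([[z0, 1e-9]])[0]
        p1 = flow.sample_pressure([[z1, 1e-9]])[0]
        expected = (p0 - p1) * TUBE_RADIUS / (2.0 * (z1 - z0))
        wss = wall_shear_stress(flow, mesh, WALL)
        mids = mesh.facet_midpoints(wss.facets)
        sel = (mids[:, 0] > z0) & (mids[:, 0] < z1)
        measured = np.sum(wss.tau[sel] * wss.areas[sel]) / \
            np.sum(wss.areas[sel])
        assert measured == pytest.approx(expected, rel=0.02)

    def test_wss_linear_in_inlet_speed_at_low_re(self, tube_mesh, rheo):
        from fddflow.hemodynamics import solve_steady
        f1 = solve_steady(tube_mesh, rheo, inlet_speed=0.001)
        f2 = solve_steady(tube_mesh, rheo, inlet_speed=0.002)
        w1 = wall_shear_stress(f1, tube_mesh, WALL)
        w2 = wall_shear_stress(f2, tube_mesh, WALL)
        sel = w1.tau > 0.2 * w1.tau.max()
        ratios = w2.tau[sel] / w1.tau[sel]
        assert np.allclose(ratios, 2.0, rtol=0.01)

    def test_untagged_surface_rejected(self, tube_flow):
        with pytest.raises(MetricError):
            wall_shear_stress(tube_flow, tube_flow.mesh, "NECK")


class TestDeltaWSS:
    def test_identical_fields_give_zero(self):
        a = _const_wss([1.0, 2.0], [1.0, 1.0])
        d = delta_wss(a, a)
        assert np.allclose(d.dwss, 0.0)

    def test_uniform_offset(self):
        pre = _const_wss([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        post = _const_wss([1.5, 2.5, 3.5], [1.0, 1.0, 1.0])
        assert np.allclose(delta_wss(pre, post).dwss, 0.5)

    def test_two_cell_example(self):
        pre = _const_wss([1.0, 3.0], [1.0, 1.0])
        post = _const_wss([2.0, 2.5], [1.0, 1.0])
        d = delta_wss(pre, post)
        assert np.allclose(d.dwss, [1.0, -0.5])
        assert max(d.dwss) == pytest.approx(1.0)

    def test_antisymmetric_under_swap(self):
        pre = _const_wss([1.0, 3.0, 0.4], [1.0, 2.0, 1.0])
        post = _const_wss([2.0, 2.5, 0.9], [1.0, 2.0, 1.0])
        assert np.allclose(delta_wss(pre, post).dwss,
                           -delta_wss(post, pre).dwss)

    def test_mismatched_surfaces_rejected(self):
        pre = _const_wss([1.0, 2.0], [1.0, 1.0])
        post = _const_wss([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        with pytest.raises(MetricError):
            delta_wss(pre, post)


class TestMaxDeltaWSS:
    def test_constant_field(self):
        f = {tp: DeltaWSSField(facets=np.array([[0, 1]]),
                               dwss=np.array([0.7]), areas=np.array([1.0]),
                               surface_tag="WALL")
             for tp in ("t1", "t2", "t3", "t4")}
        out = max_delta_wss(f)
        assert all(v == pytest.approx(0.7) for v in out.values())

    def test_spike_dominates(self):
        vals = np.array([0.1, 0.1, 5.0, 0.1])
        f = {"t1": DeltaWSSField(facets=np.arange(8).reshape(4, 2),
                                 dwss=vals, areas=np.ones(4),
                                 surface_tag="WALL")}
        assert max_delta_wss(f, time_points=("t1",))["t1"] == 5.0

    def test_missing_time_point_rejected(self):
        with pytest.raises(MetricError):
            max_delta_wss({}, time_points=("t1",))


class TestRSI:
    def test_constant_field_returns_constant(self):
        f = _const_wss([2.5, 2.5, 2.5], [0.1, 5.0, 2.2])
        assert rsi(f).rsi == pytest.approx(2.5)

    def test_area_weighted_example(self):
        f = _const_wss([2.0, 4.0], [1.0, 3.0])
        r = rsi(f)
        assert r.rsi == pytest.approx(3.5)
        assert r.force == pytest.approx(14.0)

    @given(st.floats(0.01, 10.0), st.integers(2, 30))
    @settings(deadline=None)
    def test_discretization_invariance_for_constant_fields(self, c, n):
        rng = np.random.default_rng(0)
        areas = rng.uniform(0.1, 2.0, n)
        f = _const_wss(np.full(n, c), areas)
        assert rsi(f).rsi == pytest.approx(c, rel=1e-12)

    def test_zero_area_rejected(self):
        f = _const_wss([1.0], [1.0])
        f.areas = np.array([0.0])
        with pytest.raises(MetricError):
            rsi(f)


class TestAneurysmInflow:
    def test_zero_flow(self, aneurysm_pre, rheo):
        flow = FlowField(mesh=aneurysm_pre, u=np.zeros((1, 2)),
                         p=np.zeros(aneurysm_pre.n_nodes))
        flow.u = np.zeros((flow.space.n_vnodes, 2))
        q = aneurysm_inflow(flow, aneurysm_pre, rheo.rho)
        assert q["inflow"] == 0.0 and q["net"] == 0.0

    def test_uniform_normal_velocity_closed_form(self, aneurysm_pre, rheo):
        """rho * u_n * A through the neck, reported in g/s."""
        flow = FlowField(mesh=aneurysm_pre, u=np.zeros((1, 2)),
                         p=np.zeros(aneurysm_pre.n_nodes))
        flow.u = np.tile([0.0, 0.1], (flow.space.n_vnodes, 1))
        neck_area = aneurysm_pre.facet_areas(
            aneurysm_pre.surfaces[NECK]).sum()
        q = aneurysm_inflow(flow, aneurysm_pre, rheo.rho)
        expected = 1000.0 * rheo.rho * 0.1 * neck_area
        assert q["inflow"] == pytest.approx(expected, rel=1e-9)
        assert q["net"] == pytest.approx(expected, rel=1e-9)

    def test_stent_reduces_inflow(self, aneurysm_pre, aneurysm_flow_pre,
                                  aneurysm_stented, aneurysm_flow_stented,
                                  rheo):
        q0 = aneurysm_inflow(aneurysm_flow_pre, aneurysm_pre, rheo.rho)
        q1 = aneurysm_inflow(aneurysm_flow_stented, aneurysm_stented,
                             rheo.rho)
        assert q1["inflow"] < q0["inflow"]

    def test_missing_surface_rejected(self, tube_flow):
        with pytest.raises(MetricError):
            aneurysm_inflow(tube_flow, tube_flow.mesh, 997.0)


class TestHistogram:
    def test_single_bin_collects_everything(self):
        edges, pct = histogram_percent(np.array([1.0, 1.1, 1.2]),
                                       np.array([0.0, 2.0]))
        assert pct.tolist() == [100.0]

    def test_even_split(self):
        edges, pct = histogram_percent(np.array([0.5, 1.5]),
                                       np.array([0.0, 1.0, 2.0]))
        assert pct.tolist() == [50.0, 50.0]

    def test_counting_example(self):
        edges, pct = histogram_percent(np.array([0.1, 0.2, 1.1, 2.2]),
                                       np.array([0.0, 1.0, 2.0, 3.0]))
        assert pct.tolist() == [50.0, 25.0, 25.0]

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50))
    @settings(deadline=None)
    def test_percentages_always_sum_to_100(self, vals):
        edges, pct = histogram_percent(np.array(vals),
                                       np.linspace(-1, 1, 6))
        assert pct.sum() == pytest.approx(100.0)

    def test_nonmonotone_edges_rejected(self):
        with pytest.raises(MetricError):
            histogram_percent(np.array([1.0]), np.array([0.0, 2.0, 1.0]))


class TestCompartments:
    def test_wall_compartments_partition(self, aneurysm_stented):
        mesh = aneurysm_stented
        facets = mesh.boundary[WALL]
        masks = [wall_compartment_mask(mesh, facets, c)
                 for c in ("before", "at", "after")]
        total = sum(m.sum() for m in masks)
        assert total == len(facets)
        assert all(m.any() for m in masks)
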