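"""Flow solver validation against analytic oracles and conservation laws."""

import math
from dataclasses import replace

import numpy as np
import pytest

from graftflow.exceptions import CflError, SolverError
from graftflow.geometry import StenosisSpec, build_graft, csa_profile, rasterize, straight_tube
from graftflow.metrics import (
    inlet_outlet_drop,
    peak_velocity,
    place_planes,
    plane_mean_pressure,
)
from graftflow.solver import (
    FluidProperties,
    SimulationConfig,
    check_mass_conservation,
    reynolds_number,
    simulate,
)
from graftflow.units import LPM_TO_M3S, MMHG_TO_PA, PA_TO_MMHG


class TestPoiseuille:
    """Steady Hagen-Poiseuille equivalence on the unstenosed tube."""

    def test_pressure_slope_within_2pct(self, poiseuille_run, blood):
        geom, _, _, series, q = poiseuille_run
        planes = place_planes(csa_profile(geom, 200), count=5, spacing=5e-3)
        pressures_pa = plane_mean_pressure(series, planes) * MMHG_TO_PA
        slope = np.polyfit(planes.positions, pressures_pa, 1)[0]
        slope_ref = -8.0 * blood.dynamic_viscosity * q / (
            math.pi * geom.baseline_radius**4
        )
        assert slope == pytest.approx(slope_ref, rel=0.02)

    def test_centreline_velocity_is_twice_mean(self, poiseuille_run):
        geom, _, _, series, q = poiseuille_run
        u_mean = q / (math.pi * geom.baseline_radius**2)
        assert peak_velocity(series) == pytest.approx(2.0 * u_mean, rel=0.02)

    def test_radial_profile_is_parabolic(self, poiseuille_run):
        geom, raster, _, series, q = poiseuille_run
        u_mean = q / (math.pi * geom.baseline_radius**2)
        uc, _ = series.mean_velocity_centers()
        mid = raster.nz // 2
        analytic = 2.0 * u_mean * (1.0 - (raster.r_centers / geom.baseline_radius) ** 2)
        assert np.allclose(uc[mid, :], analytic, rtol=0.03, atol=0.01 * u_mean)

    def test_plane_pressures_decrease_downstream(self, poiseuille_run):
        geom, _, _, series, _ = poiseuille_run
        planes = place_planes(csa_profile(geom, 200), count=5, spacing=5e-3)
        pressures = plane_mean_pressure(series, planes)
        assert np.all(np.diff(pressures) < 0)


class TestMassConservation:
    def test_poiseuille_flux_mismatch_below_1e3(self, poiseuille_run):
        _, _, _, series, _ = poiseuille_run
        report = check_mass_conservation(series)
        assert report.max_flux_mismatch < 1e-3
        assert report.max_divergence < 1e-6

    def test_stenosed_flux_mismatch_below_1e3(self, as2_run):
        *_, series = as2_run
        report = check_mass_conservation(series)
        assert report.max_flux_mismatch < 1e-3


class TestZeroFlow:
    def test_zero_flow_gives_rest_state(self, blood):
        raster = rasterize(straight_tube(17.5e-3, 0.05), 16)
        config = SimulationConfig(
            inlet_flow_rate=0.0,
            grid_resolution=16,
            washout_time=0.1,
            sampling_time=0.1,
            sample_interval=0.05,
        )
        series = simulate(raster, blood, config)
        assert np.max(np.abs(series.u)) < 1e-10
        assert np.max(np.abs(series.v)) < 1e-10
        assert np.allclose(series.p, config.outlet_reference_pressure, atol=1e-8)


class TestStenosedBracket:
    def test_drop_between_bernoulli_and_bernoulli_plus_poiseuille(
        self, as2_run, blood
    ):
        """Inlet-to-outlet drop on the 61% fixture sits inside the analytic
        bracket [B/2, 2(B+P)] where B is the no-recovery Bernoulli drop and P
        the unstenosed Poiseuille drop (solver tolerance factor 2)."""
        case, geom, raster, config, series = as2_run
        q = config.inlet_flow_rate
        a0 = math.pi * geom.baseline_radius**2
        a_t = geom.narrowest_csa
        v_in, v_t = q / a0, q / a_t
        bernoulli = 0.5 * blood.density * (v_t**2 - v_in**2)
        poiseuille = (
            8.0 * blood.dynamic_viscosity * geom.length * q
            / (math.pi * geom.baseline_radius**4)
        )
        drop = inlet_outlet_drop(series)
        assert bernoulli / 2.0 <= drop <= 2.0 * (bernoulli + poiseuille)


class TestScalingLaws:
    def test_viscous_drop_scales_linearly_at_low_re(self, blood):
        """At Re ~ 10-20 the drop is viscosity-dominated: doubling the flow
        roughly doubles the pressure drop."""
        geom = straight_tube(17.5e-3, 0.05)
        raster = rasterize(geom, 16)
        area = math.pi * geom.baseline_radius**2
        drops = []
        for re_target in (10.0, 20.0):
            q = re_target * blood.kinematic_viscosity / (2 * geom.baseline_radius) * area
            config = SimulationConfig(
                inlet_flow_rate=q,
                grid_resolution=16,
                washout_time=25.0,
                sampling_time=0.5,
                sample_interval=0.25,
            )
            drops.append(inlet_outlet_drop(simulate(raster, blood, config)))
        assert drops[1] / drops[0] == pytest.approx(2.0, rel=0.15)

    def test_convective_drop_scales_quadratically_at_high_re(self, blood):
        """Through a 61% stenosis at Re ~ 500-1000 the drop is convection-
        dominated: doubling the flow scales the drop by nearly four."""
        spec = StenosisSpec(0.025, 0.03, 93e-6)
        geom = build_graft(spec, 17.5e-3, 0.08)
        raster = rasterize(geom, 16)
        area = math.pi * geom.baseline_radius**2
        drops = []
        for re_target in (500.0, 1000.0):
            q = re_target * blood.kinematic_viscosity / (2 * geom.baseline_radius) * area
            config = SimulationConfig(
                inlet_flow_rate=q,
                grid_resolution=16,
                sampling_time=0.3,
            )
            drops.append(inlet_outlet_drop(simulate(raster, blood, config)))
        ratio = drops[1] / drops[0]
        assert 3.0 < ratio < 4.5


class TestGaugeInvariance:
    def test_reference_pressure_shift_leaves_velocity_unchanged(self, blood):
        raster = rasterize(straight_tube(17.5e-3, 0.05), 16)
        base = dict(
            inlet_flow_rate=1.0 * LPM_TO_M3S,
            grid_resolution=16,
            washout_time=1.0,
            sampling_time=0.2,
            sample_interval=0.1,
        )
        s1 = simulate(raster, blood, SimulationConfig(**base))
        s2 = simulate(
            raster, blood,
            SimulationConfig(**base, outlet_reference_pressure=0.0),
        )
        assert np.allclose(s1.u, s2.u, atol=1e-10)
        shift = s1.p - s2.p
        assert np.std(shift) < 1e-8  # uniform offset equal to the reference


class TestConfigAndErrors:
    def test_cfl_violation_raises(self, blood):
        raster = rasterize(straight_tube(17.5e-3, 0.05), 16)
        config = SimulationConfig(
            inlet_flow_rate=5.5 * LPM_TO_M3S,
            grid_resolution=16,
            time_step=0.05,  # grossly above the advective bound
            washout_time=0.5,
            sampling_time=0.1,
        )
        with pytest.raises((CflError, SolverError)):
            simulate(raster, blood, config)

    def test_mode_mismatch_rejected(self, blood):
        raster = rasterize(straight_tube(17.5e-3, 0.05), 16)
        config = SimulationConfig(inlet_flow_rate=0.0, mode="planar")
        with pytest.raises(SolverError):
            simulate(raster, blood, config)

    def test_invalid_fluid_rejected(self):
        with pytest.raises(SolverError):
            FluidProperties(density=-1.0)


class TestPlanarMode:
    def test_planar_channel_conserves_mass(self, blood):
        geom = straight_tube(17.5e-3, 0.05, mode_hint="planar")
        raster = rasterize(geom, 16)
        config = SimulationConfig(
            inlet_flow_rate=1e-5,
            grid_resolution=16,
            mode="planar",
            washout_time=5.0,
            sampling_time=0.2,
            sample_interval=0.1,
        )
        series = simulate(raster, blood, config)
        assert check_mass_conservation(series).max_flux_mismatch < 1e-3


class TestReynoldsNumber:
    def test_clinical_value(self, blood):
        re = reynolds_number(blood, 5.5 * LPM_TO_M3S, 17.5e-3)
        assert re == pytest.approx(2017, rel=0.01)

    def test_zero_flow_and_linearity(self, blood):
        assert reynolds_number(blood, 0.0, 17.5e-3) == 0.0
        r1 = reynolds_number(blood, 2e-5, 17.5e-3)
        r2 = reynolds_number(blood, 4e-5, 17.5e-3)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)


class TestMeshIndependence:
    def test_differences_shrink_with_refinement(self, mesh_study_table):
        diffs = mesh_study_table["diff_to_previous_mmHg"].dropna().to_numpy()
        assert len(diffs) == 2
        assert diffs[1] < diffs[0]

    def test_rejects_bad_resolution_lists(self, blood):
        from graftflow.solver import mesh_independence_study

        geom = straight_tube(17.5e-3, 0.05)
        config = SimulationConfig(inlet_flow_rate=1e-5)
        with pytest.raises(SolverError):
            mesh_independence_study(geom, blood, config, [16, 32])
        with pytest.raises(SolverError):
            mesh_independence_study(geom, blood, config, [32, 16, 48])


class TestSeriesPersistence:
    def test_save_load_round_trip(self, tmp_path, blood):
        raster = rasterize(straight_tube(17.5e-3, 0.05), 16)
        config = SimulationConfig(
            inlet_flow_rate=1.0 * LPM_TO_M3S,
            grid_resolution=16,
            washout_time=0.5,
            sampling_time=0.1,
            sample_interval=0.05,
        )
        series = simulate(raster, blood, config)
        from graftflow.solver import FlowFieldSeries

        path = tmp_path / "series.npz"
        series.save(path)
        loaded = FlowFieldSeries.load(path)
        assert np.array_equal(loaded.u, series.u)
        assert np.array_equal(loaded.p, series.p)
        assert loaded.raster.nz == series.raster.nz
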