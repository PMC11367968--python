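"""Shared fixtures: expensive simulations are session-scoped so several test
modules can interrogate the same runs."""

import math

import numpy as np
import pytest

from graftflow import (
    FluidProperties,
    SimulationConfig,
    mesh_independence_study,
    rasterize,
    simulate,
    straight_tube,
)
from graftflow.cases import make_case
from graftflow.metrics import summarize
from graftflow.sweep import run_sweep
from graftflow.units import LPM_TO_M3S

# desk-scale settings used for the severity/flow sweeps: coarse enough to keep
# a full 9-cell sweep around two minutes, fine enough to resolve every throat
SWEEP_RESOLUTION = 24
SWEEP_SAMPLING_S = 0.4


@pytest.fixture(scope="session")
def blood() -> FluidProperties:
    return FluidProperties()


@pytest.fixture(scope="session")
def poiseuille_run(blood):
    """Straight tube at Re 15, 32 cells/diameter, run to steady state.

    Returns (geometry, raster, config, series, flow_rate).
    """
    geom = straight_tube(17.5e-3, 0.06)
    raster = rasterize(geom, 32)
    area = math.pi * geom.baseline_radius**2
    q = 15.0 * blood.kinematic_viscosity / (2.0 * geom.baseline_radius) * area
    config = SimulationConfig(
        inlet_flow_rate=q,
        grid_resolution=32,
        washout_time=25.0,  # several radial diffusion times: fully developed
        sampling_time=0.5,
        sample_interval=0.1,
    )
    series = simulate(raster, blood, config)
    return geom, raster, config, series, q


@pytest.fixture(scope="session")
def as2_run(blood):
    """Case 2 AS2 (61% CSA reduction) at 5.5 L/min, the tightest condition."""
    case = make_case(2)
    geom = case.build_geometry("AS2")
    raster = rasterize(geom, SWEEP_RESOLUTION)
    config = SimulationConfig(
        inlet_flow_rate=5.5 * LPM_TO_M3S,
        grid_resolution=SWEEP_RESOLUTION,
        sampling_time=SWEEP_SAMPLING_S,
    )
    series = simulate(raster, blood, config)
    return case, geom, raster, config, series


@pytest.fixture(scope="session")
def case2_sweep(blood):
    """Full 3 severities x 3 flows sweep of the Case 2 fixture."""
    case = make_case(2)
    config = SimulationConfig(
        inlet_flow_rate=3.5 * LPM_TO_M3S,
        grid_resolution=SWEEP_RESOLUTION,
        sampling_time=SWEEP_SAMPLING_S,
    )
    return run_sweep(case, config, fluid=blood)


@pytest.fixture(scope="session")
def case1_gradients(blood):
    """Case 1 pressure gradients across severities at fixed 5.5 L/min."""
    case = make_case(1)
    grads = {}
    for severity in ("OS", "AS1", "AS2"):
        geom = case.build_geometry(severity)
        raster = rasterize(geom, SWEEP_RESOLUTION)
        config = SimulationConfig(
            inlet_flow_rate=5.5 * LPM_TO_M3S,
            grid_resolution=SWEEP_RESOLUTION,
            sampling_time=SWEEP_SAMPLING_S,
        )
        summary = summarize(simulate(raster, blood, config), blood)
        grads[severity] = summary.pressure_gradient_mmHg
    return grads


@pytest.fixture(scope="session")
def mesh_study_table(blood):
    """Grid-refinement study on the unstenosed tube at 4.5 L/min."""
    geom = straight_tube(17.49e-3, 0.1)
    config = SimulationConfig(inlet_flow_rate=4.5 * LPM_TO_M3S, sampling_time=0.5)
    return mesh_independence_study(geom, blood, config, [16, 32, 48])
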