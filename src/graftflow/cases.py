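"""Synthetic stand-ins for the two clinical cases and analytic field fixtures.

The two patients' graft geometries are emulated parametrically from the
published severity table: per case, three narrowest cross-sectional areas
(original stenosis OS and two virtually augmented severities AS1/AS2). The
unstenosed baseline area is never published; it is back-computed per case as
the mean of narrowest-CSA/(1 - fraction) over the three severities and stored
explicitly here so nothing downstream re-derives it.

Field fixtures provide analytically known velocity/pressure series (steady
Poiseuille profile, single-frequency sinusoid, seeded Gaussian fluctuations,
constants) so the metrics stage can be validated independently of the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .exceptions import GraftFlowError, GeometryError
from .geometry import (
    GraftGeometry,
    RasterizedGraft,
    StenosisSpec,
    build_graft,
    augment_stenosis,
    severity_factor_for_csa,
)
from .radiology import RadiologicalMeasurement
from .solver import FlowFieldSeries, FluidProperties, SimulationConfig
from .units import MM2_TO_M2, MM_TO_M

__all__ = [
    "CaseFixture",
    "FieldFixture",
    "SEVERITIES",
    "DEVICE_FLOWS_LPM",
    "make_case",
    "make_field_fixture",
    "make_radiology_fixture",
]

SEVERITIES = ("OS", "AS1", "AS2")
DEVICE_FLOWS_LPM = (3.5, 4.5, 5.5)

# narrowest CSA per severity (mm²) and back-computed baseline areas (mm²):
# baseline = mean over severities of CSA / (1 - printed fraction)
_CASE_TARGETS_MM2 = {1: (173.0, 136.0, 116.0), 2: (165.0, 130.0, 93.0)}
_CASE_FRACTIONS = {1: (0.28, 0.43, 0.52), 2: (0.31, 0.46, 0.61)}
_CASE_BASELINE_MM2 = {
    cid: sum(
        csa / (1.0 - frac)
        for csa, frac in zip(_CASE_TARGETS_MM2[cid], _CASE_FRACTIONS[cid])
    )
    / 3.0
    for cid in (1, 2)
}


@dataclass(frozen=True)
class CaseFixture:
    """Parametric stand-in for one patient's stenosed outflow graft.

    The stenotic segment defaults to a 45 mm extent (the span of the ten
    5 mm-apart measurement planes) centred 30 mm from the graft inlet,
    between the 20 mm and 40 mm radiological measurement sites.
    """

    case_id: int
    baseline_area_mm2: float
    severity_csa_mm2: dict[str, float]
    stenosis_center_mm: float = 30.0
    stenosis_extent_mm: float = 45.0
    graft_length_mm: float = 100.0
    curvature_radius_mm: float = math.inf
    eccentricity: float = 1.0  # one-sided extrinsic compression
    flows_lpm: tuple[float, ...] = DEVICE_FLOWS_LPM
    mode: str = "axisymmetric"

    @property
    def label(self) -> str:
        return f"Case {self.case_id}"

    @property
    def baseline_diameter_m(self) -> float:
        return 2.0 * math.sqrt(self.baseline_area_mm2 * MM2_TO_M2 / math.pi)

    def build_geometry(self, severity: str = "OS") -> GraftGeometry:
        """OS via direct construction; AS1/AS2 via stenosis augmentation."""
        if severity not in self.severity_csa_mm2:
            raise GraftFlowError(f"unknown severity {severity!r}")
        spec = StenosisSpec(
            center_position=self.stenosis_center_mm * MM_TO_M,
            axial_extent=self.stenosis_extent_mm * MM_TO_M,
            target_narrowest_csa=self.severity_csa_mm2["OS"] * MM2_TO_M2,
            eccentricity=self.eccentricity,
        )
        os_geom = build_graft(
            spec,
            baseline_diameter=self.baseline_diameter_m,
            length=self.graft_length_mm * MM_TO_M,
            curvature_radius=self.curvature_radius_mm * MM_TO_M,
            mode_hint=self.mode,
        )
        if severity == "OS":
            return os_geom
        factor = severity_factor_for_csa(
            os_geom, self.severity_csa_mm2[severity] * MM2_TO_M2
        )
        return augment_stenosis(os_geom, factor)

    def to_yaml(self, path) -> None:
        data = {
            "case_id": self.case_id,
            "baseline_area_mm2": self.baseline_area_mm2,
            "severity_csa_mm2": dict(self.severity_csa_mm2),
            "stenosis_center_mm": self.stenosis_center_mm,
            "stenosis_extent_mm": self.stenosis_extent_mm,
            "graft_length_mm": self.graft_length_mm,
            "eccentricity": self.eccentricity,
            "flows_lpm": list(self.flows_lpm),
            "mode": self.mode,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def make_case(case_id: int, **overrides) -> CaseFixture:
    """Deterministic fixture for case 1 or 2 from the published severity table."""
    if case_id not in (1, 2):
        raise GraftFlowError(f"unknown case id {case_id!r} (expected 1 or 2)")
    fixture = CaseFixture(
        case_id=case_id,
        baseline_area_mm2=_CASE_BASELINE_MM2[case_id],
        severity_csa_mm2=dict(zip(SEVERITIES, _CASE_TARGETS_MM2[case_id])),
    )
    return replace(fixture, **overrides) if overrides else fixture


# ---------------------------------------------------------------------------
# analytic / stochastic field fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldFixture:
    """Specification of a reproducible synthetic flow-field series.

    kinds: ``constant`` (params: u, v, pressure), ``poiseuille`` (params:
    flow_rate), ``sinusoidal`` (params: amplitude, frequency, n_periods,
    samples_per_period), ``gaussian-turbulence`` (params: mean_u, sigma,
    n_samples).
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def _empty_series(raster: RasterizedGraft, times: np.ndarray) -> FlowFieldSeries:
    n = len(times)
    config = SimulationConfig(inlet_flow_rate=0.0, mode=raster.mode)
    return FlowFieldSeries(
        raster=raster,
        fluid=FluidProperties(),
        config=config,
        times=times,
        u=np.zeros((n, raster.nz + 1, raster.nr)),
        v=np.zeros((n, raster.nz, raster.nr + 1)),
        p=np.full((n, raster.nz, raster.nr), config.outlet_reference_pressure),
    )


def make_field_fixture(spec: FieldFixture, raster: RasterizedGraft) -> FlowFieldSeries:
    """Materialise an analytic/stochastic series on ``raster``.

    Bit-reproducible from (kind, params, seed).
    """
    kind = spec.kind
    p = dict(spec.params)
    if kind == "constant":
        times = np.linspace(0.0, 1.0, int(p.get("n_samples", 4)))
        series = _empty_series(raster, times)
        series.u[:] = p.get("u", 0.0)
        series.v[:] = p.get("v", 0.0)
        if "pressure" in p:
            series.p[:] = p["pressure"]
        return series

    if kind == "poiseuille":
        q = float(p["flow_rate"])
        r0 = raster.geometry.baseline_radius
        u_mean = q / (math.pi * r0**2)
        profile = 2.0 * u_mean * (1.0 - (raster.r_centers / r0) ** 2)
        times = np.linspace(0.0, 1.0, int(p.get("n_samples", 2)))
        series = _empty_series(raster, times)
        series.u[:, :, :] = profile[None, None, :]
        return series

    if kind == "sinusoidal":
        amp = float(p["amplitude"])
        freq = float(p.get("frequency", 1.0))
        n_periods = p.get("n_periods", 4)
        spp = int(p.get("samples_per_period", 64))
        if abs(n_periods - round(n_periods)) > 1e-12:
            raise GraftFlowError(
                "sinusoidal fixtures must span a whole number of periods "
                "(fractional periods bias the RMS)"
            )
        n = int(round(n_periods)) * spp
        # sample at bin centres so each period is covered uniformly
        times = (np.arange(n) + 0.5) / (spp * freq)
        series = _empty_series(raster, times)
        signal = amp * np.sin(2.0 * math.pi * freq * times)
        series.u[:, :, :] = signal[:, None, None]
        return series

    if kind == "gaussian-turbulence":
        n = int(p.get("n_samples", 10_000))
        sigma = float(p["sigma"])
        mean_u = float(p.get("mean_u", 0.0))
        rng = np.random.default_rng(spec.seed)
        times = np.arange(n, dtype=float)
        series = _empty_series(raster, times)
        # three independent zero-mean components; fluctuations are spatially
        # uniform per sample so face-to-centre interpolation leaves the
        # per-cell variance untouched
        series.u[:] = mean_u + rng.normal(0.0, sigma, size=n)[:, None, None]
        series.v[:] = rng.normal(0.0, sigma, size=n)[:, None, None]
        series.w = rng.normal(0.0, sigma, size=n)[:, None, None] * np.ones(
            (1, raster.nz, raster.nr)
        )
        return series

    raise GraftFlowError(f"unknown field-fixture kind {kind!r}")


def make_radiology_fixture() -> list[RadiologicalMeasurement]:
    """The four in-study measurement sites (two per case).

    Case 1: 4/17 mm and 54/244 mm² at 20 mm; 6/17 mm and 76/259 mm² at 40 mm.
    Case 2: 9/17 mm and 85/236 mm² at 20 mm; 6/17 mm and 44/246 mm² at 40 mm.
    """
    return [
        RadiologicalMeasurement(20.0, 4.0, 17.0, 54.0, 244.0),
        RadiologicalMeasurement(40.0, 6.0, 17.0, 76.0, 259.0),
        RadiologicalMeasurement(20.0, 9.0, 17.0, 85.0, 236.0),
        RadiologicalMeasurement(40.0, 6.0, 17.0, 44.0, 246.0),
    ]
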