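"""Haemodynamic parameters extracted from a flow-field series.

The quantities mirror the clinical post-processing of stenotic graft flow:

* plane-averaged pressures in 10 evenly spaced (5 mm apart) cross-sectional
  planes over the stenotic segment;
* the pressure gradient, defined as the maximum plane-averaged mean pressure
  minus the aortic reference pressure;
* the peak velocity in the graft;
* Reynolds-decomposed velocity fluctuations, u' = sqrt((1/N) Σ (u_i - ū)²)
  per component, and the turbulent kinetic energy density
  TKE = ½ ρ (u'² + υ'² + w'²), volume-integrated over the lumen and reported
  in millijoules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import PlaneError, SolverError
from .geometry import CsaProfile
from .solver import FlowFieldSeries, FluidProperties
from .units import J_TO_MJ, PA_TO_MMHG

__all__ = [
    "PlaneSet",
    "ReynoldsStats",
    "HaemodynamicSummary",
    "place_planes",
    "plane_mean_pressure",
    "pressure_gradient",
    "peak_velocity",
    "reynolds_stats",
    "integrate_tke",
    "inlet_outlet_drop",
    "summarize",
]

DEFAULT_PLANE_COUNT = 10
DEFAULT_PLANE_SPACING = 5e-3  # m


@dataclass(frozen=True)
class PlaneSet:
    """Evenly spaced cross-sectional measurement planes."""

    positions: np.ndarray  # (count,) axial positions, m
    spacing: float

    @property
    def count(self) -> int:
        return len(self.positions)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise PlaneError("need at least one plane")
        if self.count > 1 and not np.allclose(
            np.diff(self.positions), self.spacing, rtol=1e-9, atol=1e-12
        ):
            raise PlaneError("planes must be evenly spaced")


@dataclass(frozen=True)
class ReynoldsStats:
    """Per-cell Reynolds decomposition of the sampled velocity signal.

    Components follow the solver's frame: axial (u), radial/cross-stream (υ)
    and azimuthal/out-of-plane (w, identically zero in the 2D modes). The TKE
    identity ``tke_density == ½ ρ (u'² + υ'² + w'²)`` holds exactly.
    """

    mean_u: np.ndarray
    mean_v: np.ndarray
    mean_w: np.ndarray
    u_rms: np.ndarray
    v_rms: np.ndarray
    w_rms: np.ndarray
    tke_density: np.ndarray  # J/m³
    n_samples: int


@dataclass(frozen=True)
class HaemodynamicSummary:
    """Headline metrics for one (severity, flow) condition."""

    plane_positions_m: list[float]
    plane_pressures_mmHg: list[float]
    pressure_gradient_mmHg: float
    peak_velocity_ms: float
    integrated_tke_mJ: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HaemodynamicSummary":
        with open(path) as fh:
            return cls(**json.load(fh))


def place_planes(
    csa: CsaProfile,
    count: int = DEFAULT_PLANE_COUNT,
    spacing: float = DEFAULT_PLANE_SPACING,
) -> PlaneSet:
    """Centre ``count`` planes, ``spacing`` apart, on the narrowest station.

    The stenotic segment is identified as stations whose area falls more than
    1% below the baseline (maximum) area; without one, the planes centre on
    the domain midpoint. If the span would leave the domain it is shifted
    inward, and a domain shorter than the span is an error.
    """
    lo, hi = float(csa.stations[0]), float(csa.stations[-1])
    span = (count - 1) * spacing
    if span > hi - lo:
        raise PlaneError(
            f"plane span {span:.3f} m exceeds the domain extent {hi - lo:.3f} m"
        )
    stenotic = csa.areas < 0.99 * csa.baseline_area
    center = csa.narrowest_station if np.any(stenotic) else 0.5 * (lo + hi)
    start = center - span / 2.0
    start = min(max(start, lo), hi - span)
    return PlaneSet(positions=start + spacing * np.arange(count), spacing=spacing)


def plane_mean_pressure(series: FlowFieldSeries, planes: PlaneSet) -> np.ndarray:
    """Per-plane, time-averaged, area-weighted mean pressure in mmHg.

    Each plane maps to its nearest axial cell layer; the spatial mean is
    area-weighted over the lumen cells of that layer.
    """
    raster = series.raster
    p_mean = series.mean_pressure()
    weights = raster.geom_weight_centers * raster.dr  # per-cell annulus area
    out = np.empty(planes.count)
    for k, pos in enumerate(planes.positions):
        i = int(np.clip(round(pos / raster.dz - 0.5), 0, raster.nz - 1))
        mask = raster.fluid[i, :]
        if not mask.any():
            raise PlaneError(f"plane at s={pos:.4f} m intersects no lumen cells")
        w = weights * mask
        out[k] = float(np.sum(p_mean[i, :] * w) / np.sum(w))
    return out * PA_TO_MMHG


def pressure_gradient(plane_pressures_mmHg, reference_mmHg: float = 100.0) -> float:
    """Maximum plane-averaged mean pressure minus the aortic reference (mmHg)."""
    arr = np.asarray(plane_pressures_mmHg, dtype=float)
    if arr.size == 0:
        raise PlaneError("empty plane-pressure list")
    return float(arr.max() - reference_mmHg)


def peak_velocity(series: FlowFieldSeries, mode: str = "time-mean") -> float:
    """Maximum velocity magnitude over lumen cells (m/s).

    ``time-mean`` (default) takes the maximum of the time-averaged velocity
    field; ``instantaneous`` takes the maximum over all samples.
    """
    if series.n_samples == 0:
        raise SolverError("empty series")
    mask = series.raster.fluid
    if mode == "time-mean":
        uc, vc = series.mean_velocity_centers()
        mag = np.hypot(uc, vc)
        return float(mag[mask].max()) if mask.any() else 0.0
    if mode == "instantaneous":
        best = 0.0
        for k in range(series.n_samples):
            mag = series.velocity_magnitude_centers(k)
            best = max(best, float(mag[mask].max()))
        return best
    raise ValueError(f"unknown peak-velocity mode {mode!r}")


def reynolds_stats(series: FlowFieldSeries, fluid: FluidProperties) -> ReynoldsStats:
    """Reynolds decomposition of the sampled velocity signal, per cell.

    RMS fluctuations use the population normalisation 1/N, matching the
    root-mean-square definition of u'.
    """
    n = series.n_samples
    if n < 2:
        raise SolverError("fluctuations undefined for a single-sample series")
    shape = (series.raster.nz, series.raster.nr)
    ucs = np.empty((n, *shape))
    vcs = np.empty((n, *shape))
    for k in range(n):
        ucs[k], vcs[k] = series.velocity_centers(k)
    mean_u = ucs.mean(axis=0)
    mean_v = vcs.mean(axis=0)
    u_rms = np.sqrt(np.mean((ucs - mean_u) ** 2, axis=0))
    v_rms = np.sqrt(np.mean((vcs - mean_v) ** 2, axis=0))
    if series.w is not None:
        mean_w = series.w.mean(axis=0)
        w_rms = np.sqrt(np.mean((series.w - mean_w) ** 2, axis=0))
    else:
        mean_w = np.zeros(shape)
        w_rms = np.zeros(shape)
    tke = 0.5 * fluid.density * (u_rms**2 + v_rms**2 + w_rms**2)
    return ReynoldsStats(
        mean_u=mean_u,
        mean_v=mean_v,
        mean_w=mean_w,
        u_rms=u_rms,
        v_rms=v_rms,
        w_rms=w_rms,
        tke_density=tke,
        n_samples=n,
    )


def integrate_tke(tke_density: np.ndarray, cell_volumes: np.ndarray) -> float:
    """Volume integral of TKE density, reported in millijoules."""
    if tke_density.shape != cell_volumes.shape:
        raise ValueError("field and volume shapes must match")
    return float(np.sum(tke_density * cell_volumes)) * J_TO_MJ


def inlet_outlet_drop(series: FlowFieldSeries) -> float:
    """Time-averaged pressure drop (Pa) from the first cell layer to the outlet."""
    raster = series.raster
    p_mean = series.mean_pressure()
    w = raster.geom_weight_centers * raster.dr * raster.fluid[0, :]
    p_in = float(np.sum(p_mean[0, :] * w) / np.sum(w))
    return p_in - series.config.outlet_reference_pressure


def summarize(
    series: FlowFieldSeries,
    fluid: FluidProperties,
    planes: PlaneSet | None = None,
    reference_mmHg: float | None = None,
    peak_mode: str = "time-mean",
) -> HaemodynamicSummary:
    """Full metrics pass for one run: planes, gradient, peak velocity, TKE."""
    raster = series.raster
    if planes is None:
        planes = place_planes(raster.csa_from_mask())
    if reference_mmHg is None:
        reference_mmHg = series.config.outlet_reference_pressure * PA_TO_MMHG
    plane_p = plane_mean_pressure(series, planes)
    stats = reynolds_stats(series, fluid) if series.n_samples >= 2 else None
    tke_mj = (
        integrate_tke(stats.tke_density, raster.cell_volumes * raster.fluid)
        if stats is not None
        else 0.0
    )
    return HaemodynamicSummary(
        plane_positions_m=[float(x) for x in planes.positions],
        plane_pressures_mmHg=[float(x) for x in plane_p],
        pressure_gradient_mmHg=pressure_gradient(plane_p, reference_mmHg),
        peak_velocity_ms=peak_velocity(series, mode=peak_mode),
        integrated_tke_mJ=tke_mj,
    )
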