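"""Parametric stenosed outflow-graft geometries.

The outflow graft is modelled as a straight tube of uniform baseline radius
with a localized extrinsic compression: a smooth cosine-squared bump of inward
wall displacement over a finite axial extent. Compression may be concentric
(eccentricity 0) or applied predominantly from one side (eccentricity 1, the
typical picture of material accumulating between graft and bend relief on one
wall). Severity is parameterised by the narrowest cross-sectional area (CSA),
which is the clinically reported quantity; the axisymmetric solver consumes the
area-equivalent radius profile, so concentric and eccentric variants of equal
CSA are hydraulically identical in that mode.

Axial coordinate ``s`` is in metres, 0 at the graft inlet (pump side),
increasing toward the aorta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .exceptions import GeometryError, OcclusionError, ResolutionError
from .units import M2_TO_MM2, M_TO_MM

__all__ = [
    "StenosisSpec",
    "GraftGeometry",
    "CsaProfile",
    "RasterizedGraft",
    "build_graft",
    "straight_tube",
    "augment_stenosis",
    "severity_factor_for_csa",
    "csa_profile",
    "percent_csa_reduction",
    "rasterize",
    "round_half_up",
]

#: azimuthal quadrature points for eccentric cross-section areas
_N_THETA = 721


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (clinical convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class StenosisSpec:
    """Target description of one extrinsic stenosis.

    Parameters
    ----------
    center_position : float
        Axial position of the narrowest point, metres from the graft inlet.
    axial_extent : float
        Length of the compressed segment in metres; displacement is zero
        outside ``center_position ± axial_extent/2``.
    target_narrowest_csa : float
        Narrowest lumen cross-sectional area in m².
    eccentricity : float
        Fraction in [0, 1] of the compression applied from one side
        (0 = concentric, 1 = fully one-sided).
    """

    center_position: float
    axial_extent: float
    target_narrowest_csa: float
    eccentricity: float = 0.0

    def validate(self, baseline_area: float, length: float) -> None:
        if not 0.0 < self.target_narrowest_csa < baseline_area:
            raise GeometryError(
                f"target narrowest CSA {self.target_narrowest_csa!r} m² must lie "
                f"strictly between 0 and the baseline area {baseline_area:.4e} m²"
            )
        if not 0.0 <= self.eccentricity <= 1.0:
            raise GeometryError("eccentricity must lie in [0, 1]")
        if self.axial_extent <= 0 or self.axial_extent >= length:
            raise GeometryError("axial extent must be positive and shorter than the graft")
        if not 0.0 <= self.center_position <= length:
            raise GeometryError("stenosis centre must lie inside the graft")


def _azimuthal_weight(theta: np.ndarray, eccentricity: float) -> np.ndarray:
    """Inward displacement weight over azimuth.

    Concentric limit (e=0) gives a uniform weight of 1; the fully one-sided
    limit (e=1) gives 1+cos(theta), i.e. twice the amplitude at theta=0 and
    nothing on the opposite wall. Intermediate eccentricities interpolate
    linearly, which keeps the azimuthal mean displacement equal to the scalar
    amplitude for every e.
    """
    return (1.0 - eccentricity) + eccentricity * (1.0 + np.cos(theta))


def _section_area(radius: float, amplitude: float, eccentricity: float) -> float:
    """Lumen area of one cross-section under displacement ``amplitude``."""
    if amplitude == 0.0:
        return math.pi * radius**2
    if eccentricity == 0.0:
        r = radius - amplitude
        if r <= 0:
            raise OcclusionError("compression closes the lumen")
        return math.pi * r**2
    theta = np.linspace(0.0, 2.0 * math.pi, _N_THETA)
    r = radius - amplitude * _azimuthal_weight(theta, eccentricity)
    if np.any(r <= 0):
        raise OcclusionError("compression closes the lumen")
    return float(np.trapezoid(0.5 * r**2, theta))


@dataclass(frozen=True)
class GraftGeometry:
    """A parametric stenosed graft.

    The wall displacement amplitude profile is a cosine-squared bump::

        c(s) = amplitude * cos²(π (s - s0) / extent)   for |s - s0| < extent/2

    which is continuously differentiable at the bump edges. ``radius(s)``
    returns the area-equivalent (hydraulic) radius used by the axisymmetric
    solver; for concentric compression this is simply the geometric radius.
    """

    length: float
    baseline_radius: float
    amplitude: float
    center_position: float
    axial_extent: float
    eccentricity: float = 0.0
    curvature_radius: float = math.inf
    mode_hint: str = "axisymmetric"

    def __post_init__(self) -> None:
        if self.length <= 0 or self.baseline_radius <= 0:
            raise GeometryError("length and baseline radius must be positive")
        if self.amplitude < 0:
            raise GeometryError("compression displacement must be non-negative")
        peak = self.amplitude * (1.0 + self.eccentricity)
        if peak >= self.baseline_radius:
            raise OcclusionError(
                f"peak wall displacement {peak * M_TO_MM:.2f} mm reaches the "
                f"baseline radius {self.baseline_radius * M_TO_MM:.2f} mm"
            )

    # -- profiles ----------------------------------------------------------

    def baseline_radius_profile(self, s: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(s, dtype=float), self.baseline_radius)

    def compression_displacement(self, s: np.ndarray) -> np.ndarray:
        """Scalar displacement amplitude at each axial station (m, >= 0)."""
        s = np.asarray(s, dtype=float)
        x = (s - self.center_position) / self.axial_extent
        inside = np.abs(x) < 0.5
        c = np.zeros_like(s)
        c[inside] = self.amplitude * np.cos(np.pi * x[inside]) ** 2
        return c

    def area(self, s: np.ndarray) -> np.ndarray:
        """Lumen cross-sectional area at each station (m²)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        amp = self.compression_displacement(s)
        if self.eccentricity == 0.0:
            return np.pi * (self.baseline_radius - amp) ** 2
        return np.array(
            [_section_area(self.baseline_radius, a, self.eccentricity) for a in amp]
        )

    def radius(self, s: np.ndarray) -> np.ndarray:
        """Area-equivalent lumen radius at each station (m)."""
        return np.sqrt(self.area(s) / np.pi)

    @property
    def baseline_area(self) -> float:
        return math.pi * self.baseline_radius**2

    @property
    def narrowest_csa(self) -> float:
        """Analytic narrowest CSA (bump peak sits at the stenosis centre)."""
        return float(self.area(np.array([self.center_position]))[0])


@dataclass(frozen=True)
class CsaProfile:
    """Cross-sectional areas sampled along the graft axis."""

    stations: np.ndarray  # (n,) axial positions, m, strictly increasing
    areas: np.ndarray  # (n,) lumen areas, m², all positive

    def __post_init__(self) -> None:
        if len(self.stations) != len(self.areas) or len(self.stations) < 2:
            raise GeometryError("profile needs >= 2 matched stations")
        if np.any(np.diff(self.stations) <= 0):
            raise GeometryError("stations must be strictly increasing")
        if np.any(self.areas <= 0):
            raise GeometryError("areas must be positive")

    @property
    def narrowest_csa(self) -> float:
        return float(np.min(self.areas))

    @property
    def narrowest_station(self) -> float:
        return float(self.stations[int(np.argmin(self.areas))])

    @property
    def baseline_area(self) -> float:
        return float(np.max(self.areas))

    def to_csv(self, path) -> None:
        """Write (station_m, area_mm2) rows."""
        import pandas as pd

        pd.DataFrame(
            {"station_m": self.stations, "area_mm2": self.areas * M2_TO_MM2}
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def straight_tube(
    diameter: float, length: float, mode_hint: str = "axisymmetric"
) -> GraftGeometry:
    """An unstenosed straight tube (zero compression everywhere)."""
    if diameter <= 0 or length <= 0:
        raise GeometryError("diameter and length must be positive")
    return GraftGeometry(
        length=length,
        baseline_radius=diameter / 2.0,
        amplitude=0.0,
        center_position=length / 2.0,
        axial_extent=length / 2.0,
        mode_hint=mode_hint,
    )


def build_graft(
    spec: StenosisSpec,
    baseline_diameter: float,
    length: float,
    curvature_radius: float = math.inf,
    mode_hint: str = "axisymmetric",
) -> GraftGeometry:
    """Construct a stenosed graft whose narrowest CSA hits the spec target.

    The displacement amplitude is solved so that the cross-section at the bump
    peak has exactly ``spec.target_narrowest_csa`` (analytically for concentric
    compression, by bracketing root search for eccentric sections).
    """
    if baseline_diameter <= 0:
        raise GeometryError("baseline diameter must be positive")
    radius = baseline_diameter / 2.0
    baseline_area = math.pi * radius**2
    spec.validate(baseline_area, length)

    target = spec.target_narrowest_csa
    if spec.eccentricity == 0.0:
        amplitude = radius - math.sqrt(target / math.pi)
    else:
        hi = radius / (1.0 + spec.eccentricity) * (1.0 - 1e-9)

        def f(a: float) -> float:
            return _section_area(radius, a, spec.eccentricity) - target

        if f(hi) > 0:
            raise OcclusionError("target CSA unreachable before lumen closure")
        amplitude = brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-13)

    return GraftGeometry(
        length=length,
        baseline_radius=radius,
        amplitude=float(amplitude),
        center_position=spec.center_position,
        axial_extent=spec.axial_extent,
        eccentricity=spec.eccentricity,
        curvature_radius=curvature_radius,
        mode_hint=mode_hint,
    )


def augment_stenosis(geom: GraftGeometry, severity_factor: float) -> GraftGeometry:
    """Scale the compression displacement pointwise by ``severity_factor``.

    This is the virtual stepwise-linear deformation used to generate augmented
    severities from an original stenosis: stations outside the stenotic
    segment are untouched and the narrowest point stays where it was.
    Raises :class:`OcclusionError` if the deformation would close the lumen.
    """
    if severity_factor < 1.0:
        raise GeometryError("severity factor must be >= 1")
    if severity_factor == 1.0:
        return geom
    return replace(geom, amplitude=geom.amplitude * severity_factor)


def severity_factor_for_csa(geom: GraftGeometry, target_csa: float) -> float:
    """Severity factor that makes ``augment_stenosis`` hit ``target_csa``."""
    if not 0.0 < target_csa <= geom.narrowest_csa:
        raise GeometryError(
            "augmentation target CSA must be positive and no larger than the "
            "current narrowest CSA"
        )
    if geom.amplitude == 0.0:
        raise GeometryError("geometry has no stenosis to augment")
    if geom.eccentricity == 0.0:
        needed = geom.baseline_radius - math.sqrt(target_csa / math.pi)
        return needed / geom.amplitude
    hi = geom.baseline_radius / (1.0 + geom.eccentricity) / geom.amplitude * (1.0 - 1e-9)

    def f(factor: float) -> float:
        return (
            _section_area(
                geom.baseline_radius, geom.amplitude * factor, geom.eccentricity
            )
            - target_csa
        )

    return float(brentq(f, 1.0, hi, xtol=1e-12, rtol=1e-13))


def csa_profile(geom: GraftGeometry, n_stations: int) -> CsaProfile:
    """Sample the cross-sectional-area profile at cell-centred stations."""
    if n_stations < 2:
        raise GeometryError("need at least 2 stations")
    ds = geom.length / n_stations
    stations = (np.arange(n_stations) + 0.5) * ds
    return CsaProfile(stations=stations, areas=geom.area(stations))


def percent_csa_reduction(narrowest: float, baseline: float) -> int:
    """Percent lumen reduction, rounded half-up to the nearest integer."""
    if baseline <= 0:
        raise GeometryError("baseline area must be positive")
    if not 0.0 < narrowest <= baseline:
        raise GeometryError("narrowest CSA must be in (0, baseline]")
    return round_half_up(100.0 * (1.0 - narrowest / baseline))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RasterizedGraft:
    """Structured-grid representation of a graft for the flow solver.

    Axisymmetric mode: an r-z grid over half the meridional plane
    (0 <= r <= baseline radius). Planar mode: the same arrays reinterpreted as
    a symmetric half-channel in x-y (per metre of depth). ``open_fraction``
    stores, per cell, the fraction of the cell's radial span inside the lumen
    (a cut-cell area fraction); the binary ``fluid`` mask used by the solver
    marks cells whose centre lies inside the lumen (stair-step wall).
    """

    mode: str
    dr: float
    dz: float
    nr: int
    nz: int
    radius: np.ndarray  # (nz,) analytic lumen radius at axial cell centres
    open_fraction: np.ndarray  # (nz, nr)
    fluid: np.ndarray  # (nz, nr) bool
    geometry: GraftGeometry = field(repr=False)
    resolution: int = 0

    @property
    def r_faces(self) -> np.ndarray:
        return np.arange(self.nr + 1) * self.dr

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    @property
    def geom_weight_faces(self) -> np.ndarray:
        """Radial metric weight at radial faces (r in axisymmetric, 1 planar)."""
        if self.mode == "axisymmetric":
            return self.r_faces
        return np.ones(self.nr + 1)

    @property
    def geom_weight_centers(self) -> np.ndarray:
        if self.mode == "axisymmetric":
            return self.r_centers
        return np.ones(self.nr)

    @property
    def cell_volumes(self) -> np.ndarray:
        """(nz, nr) cell volumes; axisymmetric 2π r dr dz, planar dr dz per m."""
        if self.mode == "axisymmetric":
            return np.broadcast_to(
                2.0 * np.pi * self.r_centers[None, :] * self.dr * self.dz,
                (self.nz, self.nr),
            ).copy()
        return np.full((self.nz, self.nr), self.dr * self.dz)

    def csa_from_mask(self) -> CsaProfile:
        """Lumen area per axial station recovered from the raster itself.

        Uses the cut-cell open fractions, so the recovered areas converge at
        second order to the analytic profile.
        """
        if self.mode == "axisymmetric":
            areas = 2.0 * np.pi * self.dr * (
                self.open_fraction * self.r_centers[None, :]
            ).sum(axis=1)
        else:
            # symmetric half-channel; full-channel width per metre of depth
            areas = 2.0 * self.dr * self.open_fraction.sum(axis=1)
        return CsaProfile(stations=self.z_centers, areas=areas)

    def wall_position(self) -> np.ndarray:
        """(nz,) stair-step wall radius implied by the binary fluid mask."""
        return self.fluid.sum(axis=1) * self.dr


def rasterize(geom: GraftGeometry, resolution: int) -> RasterizedGraft:
    """Rasterize a graft onto the solver's structured grid.

    ``resolution`` counts cells per baseline diameter; the radial spacing is
    chosen so the unstenosed wall falls exactly on a grid face.
    """
    if resolution < 8:
        raise ResolutionError("need at least 8 cells per baseline diameter")
    nr = int(math.ceil(resolution / 2))
    dr = geom.baseline_radius / nr
    dz = dr
    nz = max(int(round(geom.length / dz)), 4)

    z_c = (np.arange(nz) + 0.5) * dz
    radius = geom.radius(z_c)
    throat_cells = 2.0 * radius.min() / dr
    if throat_cells < 4.0:
        raise ResolutionError(
            f"only {throat_cells:.1f} cells across the narrowest lumen; "
            "refine the grid (need >= 4)"
        )

    r_f = np.arange(nr + 1) * dr
    open_fraction = np.clip((radius[:, None] - r_f[None, :-1]) / dr, 0.0, 1.0)
    fluid = open_fraction >= 0.5
    return RasterizedGraft(
        mode=geom.mode_hint,
        dr=dr,
        dz=dz,
        nr=nr,
        nz=nz,
        radius=radius,
        open_fraction=open_fraction,
        fluid=fluid,
        geometry=geom,
        resolution=resolution,
    )
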