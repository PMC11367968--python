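"""Export helpers: STL surfaces, legacy-VTK structured grids, CSV tables.

Writers are deliberately minimal: an ASCII/binary STL surface of revolution
for visual inspection of a graft, and ASCII legacy-VTK structured points of
the meridional (r-z) plane so third-party viewers can render field data.
"""

from __future__ import annotations

import struct

import numpy as np

from .geometry import GraftGeometry
from .solver import FlowFieldSeries

__all__ = ["write_stl", "write_vtk_plane", "tube_surface_mesh"]


def tube_surface_mesh(
    geom: GraftGeometry, n_axial: int = 120, n_theta: int = 48
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated lumen surface (vertices, triangle index triples).

    Uses the area-equivalent radius profile, so eccentric geometries render
    as their hydraulically equivalent concentric shape.
    """
    s = np.linspace(0.0, geom.length, n_axial)
    r = geom.radius(s)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    verts = np.empty((n_axial * n_theta, 3))
    for i in range(n_axial):
        verts[i * n_theta : (i + 1) * n_theta, 0] = s[i]
        verts[i * n_theta : (i + 1) * n_theta, 1] = r[i] * np.cos(theta)
        verts[i * n_theta : (i + 1) * n_theta, 2] = r[i] * np.sin(theta)
    tris = []
    for i in range(n_axial - 1):
        for k in range(n_theta):
            a = i * n_theta + k
            b = i * n_theta + (k + 1) % n_theta
            c = a + n_theta
            d = b + n_theta
            tris.append((a, b, c))
            tris.append((b, d, c))
    return verts, np.asarray(tris, dtype=int)


def _facet_normal(p0, p1, p2) -> np.ndarray:
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n)
    return n / norm if norm > 0 else n


def write_stl(geom: GraftGeometry, path, binary: bool = False,
              n_axial: int = 120, n_theta: int = 48) -> None:
    """Write the graft lumen surface as an STL file (ASCII or binary)."""
    verts, tris = tube_surface_mesh(geom, n_axial=n_axial, n_theta=n_theta)
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"graftflow surface".ljust(80, b"\0"))
            fh.write(struct.pack("<I", len(tris)))
            for a, b, c in tris:
                n = _facet_normal(verts[a], verts[b], verts[c])
                fh.write(struct.pack("<3f", *n))
                for p in (verts[a], verts[b], verts[c]):
                    fh.write(struct.pack("<3f", *p))
                fh.write(struct.pack("<H", 0))
        return
    with open(path, "w") as fh:
        fh.write("solid graftflow\n")
        for a, b, c in tris:
            n = _facet_normal(verts[a], verts[b], verts[c])
            fh.write(f"  facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}\n")
            fh.write("    outer loop\n")
            for p in (verts[a], verts[b], verts[c]):
                fh.write(f"      vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid graftflow\n")


def write_vtk_plane(series: FlowFieldSeries, path, sample: int | None = None) -> None:
    """Write one meridional-plane field snapshot as ASCII legacy VTK.

    ``sample=None`` writes the time-averaged fields. Point data: pressure
    (Pa), velocity (m/s, axial/radial/0) and the lumen mask.
    """
    raster = series.raster
    nz, nr = raster.nz, raster.nr
    if sample is None:
        p = series.mean_pressure()
        uc, vc = series.mean_velocity_centers()
    else:
        p = series.p[sample]
        uc, vc = series.velocity_centers(sample)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("graftflow meridional plane\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nz} {nr} 1\n")
        fh.write(f"ORIGIN {raster.dz / 2:.9e} {raster.dr / 2:.9e} 0.0\n")
        fh.write(f"SPACING {raster.dz:.9e} {raster.dr:.9e} 1.0\n")
        fh.write(f"POINT_DATA {nz * nr}\n")
        fh.write("SCALARS pressure_Pa double 1\nLOOKUP_TABLE default\n")
        for j in range(nr):
            fh.write(" ".join(f"{p[i, j]:.9e}" for i in range(nz)) + "\n")
        fh.write("SCALARS lumen int 1\nLOOKUP_TABLE default\n")
        for j in range(nr):
            fh.write(" ".join(str(int(raster.fluid[i, j])) for i in range(nz)) + "\n")
        fh.write("VECTORS velocity_ms double\n")
        for j in range(nr):
            for i in range(nz):
                fh.write(f"{uc[i, j]:.9e} {vc[i, j]:.9e} 0.0\n")
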