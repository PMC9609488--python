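"""Readers and writers for the package's text formats.

Histograms are two-column delimited text (bin center, value); '#' starts a
comment, an optional non-numeric header line is skipped, and angle files are
in degrees (converted to radians on read).  Geometry goes out as extended
XYZ (with a radius column) and legacy ASCII VTK; tables as CSV.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from fibergen.distributions import HistogramDensity
from fibergen.network import FiberNetwork
from fibergen.pores import PoreSet, VoxelGrid


def read_histogram(path: str | Path, angles_in_degrees: bool = False) -> HistogramDensity:
    """Read a (bin center, value) histogram; optionally convert deg → rad."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError):
            if rows:
                raise ValueError(f"malformed histogram line: {line!r}")
            continue  # header line
    if not rows:
        raise ValueError(f"no histogram data in {path}")
    centers = np.array([r[0] for r in rows])
    values = np.array([r[1] for r in rows])
    if angles_in_degrees:
        centers = np.deg2rad(centers)
    return HistogramDensity(centers, values)


def write_histogram(path: str | Path, centers: np.ndarray, values: np.ndarray,
                    header: str = "", angles_in_degrees: bool = False) -> None:
    centers = np.asarray(centers, dtype=float)
    if angles_in_degrees:
        centers = np.rad2deg(centers)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for c, v in zip(centers, values):
            fh.write(f"{float(c)!r}\t{float(v)!r}\n")


def write_fiber_table(path: str | Path, network: FiberNetwork) -> None:
    """Prescribed and realized per-fiber values as CSV."""
    pres = network.prescribed.add_prefix("prescribed_")
    real = network.realized_table().add_prefix("realized_")
    table = pd.concat([pres, real], axis=1)
    table.insert(0, "fiber_id", np.arange(len(table)))
    table.to_csv(path, index=False, float_format="%.17g")


def read_fiber_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_xyz(path: str | Path, positions: np.ndarray, radii: np.ndarray | None = None,
              comment: str = "fibergen particles") -> None:
    """Extended XYZ with an optional per-particle radius column."""
    positions = np.atleast_2d(positions)
    with open(path, "w") as fh:
        fh.write(f"{positions.shape[0]}\n{comment}\n")
        for i, p in enumerate(positions):
            if radii is not None:
                fh.write(f"C {float(p[0])!r} {float(p[1])!r} {float(p[2])!r} {float(radii[i])!r}\n")
            else:
                fh.write(f"C {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")


def write_vtk_polylines(path: str | Path, network: FiberNetwork) -> None:
    """Legacy ASCII VTK polydata: one polyline per fiber, radius as point data."""
    points = []
    lines = []
    radii = []
    offset = 0
    for f in network.fibers:
        n = f.points.shape[0]
        points.append(f.points)
        radii.extend([f.diameter / 2.0] * n)
        lines.append([n] + list(range(offset, offset + n)))
        offset += n
    pts = np.vstack(points)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfibergen fiber network\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {pts.shape[0]} float\n")
        for p in pts:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        total = sum(len(l) for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(str(x) for x in l) + "\n")
        fh.write(f"POINT_DATA {pts.shape[0]}\nSCALARS radius float 1\nLOOKUP_TABLE default\n")
        for r in radii:
            fh.write(f"{r:.9g}\n")


def write_vtk_image(path: str | Path, grid: VoxelGrid, field: str = "occupancy") -> None:
    """Legacy ASCII VTK structured points for occupancy or EDT volumes."""
    data = grid.occupancy.astype(float) if field == "occupancy" else grid.edt
    if data is None:
        raise ValueError("grid has no EDT; run distance_transform first")
    nx, ny, nz = data.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfibergen voxel grid\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN 0 0 0\nSPACING {float(grid.edge)!r} {float(grid.edge)!r} {float(grid.edge)!r}\n")
        fh.write(f"POINT_DATA {data.size}\nSCALARS {field} float 1\nLOOKUP_TABLE default\n")
        flat = data.reshape(-1, order="F")
        for chunk in range(0, flat.size, 9):
            fh.write(" ".join(f"{v:.7g}" for v in flat[chunk:chunk + 9]) + "\n")


def write_pores(path: str | Path, pores: PoreSet) -> None:
    df = pd.DataFrame(
        {
            "x": pores.centers[:, 0] if pores.n_pores else [],
            "y": pores.centers[:, 1] if pores.n_pores else [],
            "z": pores.centers[:, 2] if pores.n_pores else [],
            "dp": pores.diameters,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_pfo_trace(path: str | Path, trace: np.ndarray) -> None:
    pd.DataFrame(trace, columns=["step", "pfo_percent"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_fit_report(path: str | Path, report: dict) -> None:
    """Delimited fit report: kernel angle (deg), shape k2d, measured k2d, k3d."""
    with open(path, "w") as fh:
        fh.write(f"# scaling_mode: {report['scaling_mode']}\n")
        fh.write(f"# psi_deg: {math.degrees(report['psi']):.6g}\n")
        fh.write(f"# residual: {report['residual']:.9g}\n")
        fh.write("kernel_angle_deg,k2d_shape,k2d_measured,k3d\n")
        for (theta, k_shape), k_meas, k3 in zip(
            report["kernels2d"], report["k2d_measured"], report["k3d"]
        ):
            fh.write(f"{math.degrees(theta):.6g},{k_shape:.6g},{k_meas:.6g},{k3:.6g}\n")
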