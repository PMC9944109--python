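"""Mesh and field export.

STL export goes through trimesh; voxel labels and solved fields are
written as legacy-ASCII VTK structured points (readable by ParaView and
friends), and domains/fields persist as NPZ containers via their own
``save``/``load`` methods.
"""

from __future__ import annotations

import numpy as np

from .domain import VoxelDomain
from .flow import FlowField
from .geometry import SurfaceMesh

__all__ = ["export_stl", "write_vtk_labels", "write_vtk_field", "write_convergence_csv"]


def export_stl(mesh: SurfaceMesh, path, ascii: bool = False) -> None:
    """Write a surface mesh as binary (default) or ASCII STL."""
    tm = mesh.to_trimesh()
    tm.export(str(path), file_type="stl_ascii" if ascii else "stl")


def _vtk_header(fh, domain: VoxelDomain, title: str) -> None:
    nx, ny, nz = domain.shape
    s = domain.spacing
    o = domain.origin
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")
    fh.write("DATASET STRUCTURED_POINTS\n")
    # point-per-voxel-centre representation
    fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
    fh.write(f"ORIGIN {o[0]} {o[1]} {o[2]}\n")
    fh.write(f"SPACING {s} {s} {s}\n")
    fh.write(f"POINT_DATA {nx * ny * nz}\n")


def _write_scalars(fh, name: str, data: np.ndarray, fmt: str = "%g") -> None:
    fh.write(f"SCALARS {name} {'int' if data.dtype.kind == 'i' else 'float'} 1\n")
    fh.write("LOOKUP_TABLE default\n")
    # VTK structured points vary x fastest
    flat = np.asarray(data).transpose(2, 1, 0).ravel()
    np.savetxt(fh, flat.reshape(-1, 1), fmt=fmt)


def write_vtk_labels(domain: VoxelDomain, path) -> None:
    """Voxel labels as a VTK structured-points file."""
    with open(path, "w") as fh:
        _vtk_header(fh, domain, "tpmsflow voxel labels")
        _write_scalars(fh, "labels", domain.labels.astype(np.int32), fmt="%d")


def write_vtk_field(field: FlowField, domain: VoxelDomain, path) -> None:
    """Velocity (m/s), speed and pressure (Pa) as a VTK structured-points file."""
    nx, ny, nz = domain.shape
    with open(path, "w") as fh:
        _vtk_header(fh, domain, "tpmsflow flow field")
        _write_scalars(fh, "labels", domain.labels.astype(np.int32), fmt="%d")
        pressure = np.where(np.isfinite(field.pressure), field.pressure, 0.0)
        _write_scalars(fh, "pressure_pa", pressure)
        _write_scalars(fh, "speed_mps", field.speed())
        fh.write("VECTORS velocity_mps float\n")
        flat = field.velocity.transpose(2, 1, 0, 3).reshape(-1, 3)
        np.savetxt(fh, flat, fmt="%g")


def write_convergence_csv(field: FlowField, path) -> None:
    """Residual/imbalance history of a solve as CSV."""
    with open(path, "w") as fh:
        fh.write("iteration,residual,flux_imbalance\n")
        for step, res, imb in field.residual_history:
            fh.write(f"{step},{res!r},{imb!r}\n")
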