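"""Implicit TPMS fields and flow-channel geometry.

Triply periodic minimal surfaces (TPMS) are modelled through the standard
trigonometric approximation: a level set of a sum of plane-wave cosines,

    phi(r) = sum_k A_k cos(2 pi (h_k . r) / lambda_k + p_k) = C,

where ``A_k`` is an amplitude, ``h_k`` an integer reciprocal-lattice
vector, ``lambda_k`` a wavelength (mm) and ``p_k`` a phase.  The Schwarz
P surface used as the pore-forming unit of the vascular-like scaffold is
the special case

    cos x + cos y + cos z + 0.5 = 0,

i.e. three unit-amplitude axis terms with a level constant of -0.5.

The module evaluates such fields, voxelizes a slab-with-ports flow channel
into fluid/solid labels, measures porosity, and extracts triangulated
iso-surfaces (marching cubes) with area/volume measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage import measure

from .domain import (
    EXTERIOR,
    FLUID,
    INLET,
    OUTLET,
    SOLID,
    NoPercolationError,
    VoxelDomain,
)

__all__ = [
    "TPMSTerm",
    "TPMSSpec",
    "ChannelLayout",
    "SurfaceMesh",
    "evaluate_p_surface",
    "evaluate_tpms",
    "build_domain",
    "measure_porosity",
    "extract_surface",
    "sample_tpms_grid",
]


class EmptySurfaceError(ValueError):
    """The sampled field never crosses the requested iso-level."""


@dataclass(frozen=True)
class TPMSTerm:
    """One cosine summand of the periodic-surface approximation."""

    amplitude: float
    lattice_vector: tuple[int, int, int]
    wavelength: float  # mm
    phase: float = 0.0  # radians

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")


@dataclass
class TPMSSpec:
    """A TPMS implicit-field family plus its fluid/solid decision rule.

    ``mode='network'`` keeps one labyrinth of the level set as pore space
    (the side selected by ``fluid_sign``); ``mode='sheet'`` thickens the
    surface itself into the solid: voxels with ``|phi - C| <=
    half_thickness`` become scaffold material and both labyrinths stay
    fluid.
    """

    terms: tuple[TPMSTerm, ...]
    level_constant: float = 0.0
    mode: str = "network"
    fluid_sign: str = "nonnegative"
    half_thickness: float = 0.3  # dimensionless field units, sheet mode only

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        if len(self.terms) < 1:
            raise ValueError("a TPMS spec needs at least one term")
        if self.mode not in ("network", "sheet"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fluid_sign not in ("nonnegative", "negative"):
            raise ValueError(f"unknown fluid_sign {self.fluid_sign!r}")
        if self.mode == "sheet" and not self.half_thickness > 0:
            raise ValueError("half_thickness must be positive in sheet mode")

    @classmethod
    def p_surface(
        cls,
        wavelength: float = 5.0,
        mode: str = "network",
        fluid_sign: str = "nonnegative",
        half_thickness: float = 0.3,
    ) -> "TPMSSpec":
        """Schwarz P preset: ``cos x + cos y + cos z = -0.5`` at period ``wavelength``."""
        terms = tuple(
            TPMSTerm(1.0, h, wavelength, 0.0)
            for h in ((1, 0, 0), (0, 1, 0), (0, 0, 1))
        )
        return cls(
            terms=terms,
            level_constant=-0.5,
            mode=mode,
            fluid_sign=fluid_sign,
            half_thickness=half_thickness,
        )

    def fluid_where(self, values: np.ndarray) -> np.ndarray:
        """Boolean pore mask from field-minus-level values."""
        if self.mode == "network":
            if self.fluid_sign == "nonnegative":
                return values >= 0.0
            return values < 0.0
        return np.abs(values) > self.half_thickness


def _check_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 3:
        raise ValueError("points must have a trailing dimension of 3")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts


def evaluate_p_surface(points, wavelength: float) -> np.ndarray:
    """Schwarz P field ``cos(2 pi x/lam) + cos(2 pi y/lam) + cos(2 pi z/lam) + 0.5``.

    Positive values lie in the majority labyrinth (the default pore
    network); the surface itself is the zero level set.
    """
    if not wavelength > 0:
        raise ValueError("wavelength must be positive")
    pts = _check_points(points)
    k = 2.0 * np.pi / wavelength
    return (
        np.cos(k * pts[..., 0])
        + np.cos(k * pts[..., 1])
        + np.cos(k * pts[..., 2])
        + 0.5
    )


def evaluate_tpms(spec: TPMSSpec, points) -> np.ndarray:
    """Evaluate ``phi(r) - C`` for a general TPMS spec.

    The sign of the result drives the network-mode fluid/solid rule; the
    zero set is the surface.
    """
    pts = _check_points(points)
    out = np.full(pts.shape[:-1], -spec.level_constant, dtype=float)
    for term in spec.terms:
        h = np.asarray(term.lattice_vector, dtype=float)
        arg = 2.0 * np.pi * (pts @ h) / term.wavelength + term.phase
        out += term.amplitude * np.cos(arg)
    return out


@dataclass
class ChannelLayout:
    """Slab-with-ports flow channel: a rectangular scaffold slab with one
    cylindrical inlet and one outlet port on opposing x-faces.

    Defaults follow the vascular-like channel model: 66 x 30 x 10 mm slab
    with 3.08 mm diameter ports, centred on the y-z midplane of each end
    face.
    """

    slab_length: float = 66.0  # mm, x
    slab_width: float = 30.0  # mm, y
    slab_height: float = 10.0  # mm, z
    port_diameter: float = 3.08  # mm
    port_length: float = 2.0  # mm
    inlet_center: tuple[float, float] | None = None  # (y, z) mm
    outlet_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("slab_length", "slab_width", "slab_height", "port_diameter", "port_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.port_diameter > min(self.slab_width, self.slab_height):
            raise ValueError("port_diameter must fit within the slab cross-section")
        if self.inlet_center is None:
            self.inlet_center = (self.slab_width / 2.0, self.slab_height / 2.0)
        if self.outlet_center is None:
            self.outlet_center = (self.slab_width / 2.0, self.slab_height / 2.0)


def build_domain(
    spec: TPMSSpec,
    layout: ChannelLayout,
    spacing: float,
    lattice_origin: tuple[float, float, float] | None = None,
) -> VoxelDomain:
    """Voxelize the slab-with-ports channel into fluid/solid labels.

    Each voxel is classified by the field sign at its centre.  By default
    the TPMS lattice is centred on the slab (``lattice_origin`` = slab
    centre), which places a pore node at the slab midpoint and guarantees
    an open axial channel through the port axis for the Schwarz P preset.

    Raises
    ------
    NoPercolationError
        If no face-connected fluid path joins the inlet cap to the outlet
        cap after voxelization.
    """
    L, W, H = layout.slab_length, layout.slab_width, layout.slab_height
    if spacing > min(L, W, H):
        raise ValueError("spacing exceeds the smallest slab dimension")
    if spacing > min(L, W, H) / 4.0:
        raise ValueError("spacing must be at most min slab dimension / 4")
    if layout.port_diameter / spacing < 4.0:
        warnings.warn(
            f"port resolved by only {layout.port_diameter / spacing:.1f} voxels "
            "across its diameter (< 4): expect a blocky port",
            stacklevel=2,
        )

    pl = layout.port_length
    nx = int(round((L + 2 * pl) / spacing))
    ny = int(round(W / spacing))
    nz = int(round(H / spacing))
    origin = np.array([-pl + spacing / 2.0, spacing / 2.0, spacing / 2.0])

    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nz)

    labels = np.full((nx, ny, nz), EXTERIOR, dtype=np.int8)

    # slab voxels: centre inside [0, L] x [0, W] x [0, H]
    slab_i = np.nonzero((xs > 0.0) & (xs < L))[0]
    i0, i1 = int(slab_i[0]), int(slab_i[-1]) + 1

    if lattice_origin is None:
        lattice_origin = (L / 2.0, W / 2.0, H / 2.0)
    lo = np.asarray(lattice_origin, dtype=float)

    X, Y, Z = np.meshgrid(xs[i0:i1], ys, zs, indexing="ij")
    pts = np.stack([X - lo[0], Y - lo[1], Z - lo[2]], axis=-1)
    values = evaluate_tpms(spec, pts)
    slab_labels = np.where(spec.fluid_where(values), FLUID, SOLID).astype(np.int8)
    labels[i0:i1] = slab_labels

    # cylindrical ports along x on both end faces
    r = layout.port_diameter / 2.0
    for which, centre, cap_index, port_cols in (
        (INLET, layout.inlet_center, 0, range(0, i0)),
        (OUTLET, layout.outlet_center, nx - 1, range(i1, nx)),
    ):
        cy, cz = centre
        disc = (ys[:, None] - cy) ** 2 + (zs[None, :] - cz) ** 2 <= r**2
        for i in port_cols:
            labels[i][disc] = FLUID
        labels[cap_index][disc] = which

    domain = VoxelDomain(
        labels=labels,
        spacing=spacing,
        origin=origin,
        meta={
            "slab_index_box": [[i0, i1], [0, ny], [0, nz]],
            "layout": {
                "slab_length_mm": L,
                "slab_width_mm": W,
                "slab_height_mm": H,
                "port_diameter_mm": layout.port_diameter,
                "port_length_mm": layout.port_length,
            },
            "lattice_origin_mm": list(map(float, lo)),
        },
    )
    domain.require_percolation()
    return domain


def measure_porosity(domain: VoxelDomain) -> float:
    """Fluid fraction of the scaffold slab: FLUID voxels / (FLUID + SOLID) voxels.

    EXTERIOR voxels inside the slab box (material trimmed away by
    pruning) do not count toward either side, so porosity always refers
    to the remaining model footprint.
    """
    from .domain import slab_box

    region = domain.labels[slab_box(domain)]
    n_fluid = int(np.count_nonzero(region == FLUID))
    n_solid = int(np.count_nonzero(region == SOLID))
    if n_fluid + n_solid == 0:
        raise ValueError("domain has no slab voxels")
    return n_fluid / (n_fluid + n_solid)


@dataclass
class SurfaceMesh:
    """Triangulated iso-surface with its measured area and enclosed volume."""

    vertices: np.ndarray  # (n, 3) mm
    triangles: np.ndarray  # (m, 3) int
    total_area: float = dc_field(init=False)  # mm^2
    enclosed_volume: float = dc_field(init=False)  # mm^3

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.total_area = float(
            measure.mesh_surface_area(self.vertices, self.triangles)
        )
        v0 = self.vertices[self.triangles[:, 0]]
        v1 = self.vertices[self.triangles[:, 1]]
        v2 = self.vertices[self.triangles[:, 2]]
        # divergence theorem over oriented triangles; orientation from
        # marching cubes is consistent, so only the global sign is dropped
        signed = np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0
        self.enclosed_volume = float(abs(signed))

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )


def sample_tpms_grid(
    spec: TPMSSpec,
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    spacing: float,
    lattice_origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``phi - C`` on a regular grid; returns (field, origin)."""
    axes = [
        np.arange(lo + spacing / 2.0, hi, spacing) for (lo, hi) in bounds
    ]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    lo = np.asarray(lattice_origin, dtype=float)
    pts = np.stack([X - lo[0], Y - lo[1], Z - lo[2]], axis=-1)
    origin = np.array([a[0] for a in axes])
    return evaluate_tpms(spec, pts), origin


def extract_surface(
    source,
    spacing: float | None = None,
    level: float = 0.0,
    bounds=None,
    pad: bool = True,
) -> SurfaceMesh:
    """Extract the triangulated iso-surface of an implicit field.

    ``source`` may be a sampled 3D field array (with ``spacing``), a
    :class:`TPMSSpec` (with ``bounds`` and ``spacing``; the field is
    sampled here), or a :class:`VoxelDomain` (the fluid indicator is
    contoured at 0 between fluid and non-fluid voxels).

    With ``pad=True`` the sampled field is wrapped in one layer of
    below-level values so the extracted surface is watertight and the
    enclosed volume (divergence theorem) is meaningful.
    """
    if isinstance(source, TPMSSpec):
        if bounds is None or spacing is None:
            raise ValueError("TPMSSpec source needs bounds and spacing")
        field, _ = sample_tpms_grid(source, bounds, spacing)
    elif isinstance(source, VoxelDomain):
        field = np.where(source.active_mask, 1.0, -1.0)
        spacing = source.spacing
    else:
        field = np.asarray(source, dtype=float)
        if spacing is None:
            raise ValueError("field-array source needs spacing")

    if field.max() < level or field.min() > level:
        raise EmptySurfaceError("field does not cross the iso-level")

    if pad:
        field = np.pad(field, 1, constant_values=level - 1.0)

    verts, faces, _, _ = measure.marching_cubes(
        field, level=level, spacing=(spacing, spacing, spacing)
    )
    return SurfaceMesh(vertices=verts, triangles=faces)
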