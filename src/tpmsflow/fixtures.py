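"""Deterministic benchmark geometries.

Every domain a test or validation run needs is generated here from code:
analytic benchmarks (cylindrical tube for Hagen-Poiseuille, plane channel
for plane Poiseuille), a cul-de-sac channel whose side pocket is a
ground-truth dead zone, periodic TPMS blocks for porosity oracles, and a
scaled-down analogue of the 66 x 30 x 10 mm vascular-like scaffold slab
with 3.08 mm ports.  All fixtures are byte-deterministic given their
parameters; the only randomness anywhere is the seeded Monte-Carlo
porosity oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .domain import EXTERIOR, FLUID, INLET, OUTLET, SOLID, VoxelDomain
from .geometry import ChannelLayout, TPMSSpec, build_domain, evaluate_tpms

__all__ = [
    "FixtureSpec",
    "make_tube",
    "make_plane_channel",
    "make_cul_de_sac",
    "make_tpms_block",
    "make_scaled_slab",
    "monte_carlo_porosity",
    "pocket_mask",
    "make_fixture",
]


def make_tube(
    radius_mm: float = 1.0, length_mm: float = 10.0, spacing_mm: float = 0.1
) -> VoxelDomain:
    """Cylinder of fluid along x with inlet/outlet end caps and a solid sheath.

    The tube axis passes through voxel centres, and a voxel is fluid when
    its centre lies within the radius; with halfway bounce-back the
    effective wall sits mid-link just outside the outermost fluid ring.
    """
    if min(radius_mm, length_mm, spacing_mm) <= 0:
        raise ValueError("all tube dimensions must be positive")
    dx = spacing_mm
    if 2 * radius_mm / dx < 10:
        warnings.warn(
            f"tube resolved by only {2 * radius_mm / dx:.1f} voxels across the "
            "diameter (< 10): too coarse for validation use",
            stacklevel=2,
        )
    nx = int(round(length_mm / dx))
    n_r = int(np.ceil(radius_mm / dx))
    ny = nz = 2 * n_r + 3
    c = ny * dx / 2.0  # axis on a voxel centre (ny odd)

    ys = (np.arange(ny) + 0.5) * dx
    zs = (np.arange(nz) + 0.5) * dx
    disc = (ys[:, None] - c) ** 2 + (zs[None, :] - c) ** 2 <= radius_mm**2

    labels = np.full((nx, ny, nz), SOLID, dtype=np.int8)
    labels[:, disc] = FLUID
    labels[0, disc] = INLET
    labels[-1, disc] = OUTLET

    domain = VoxelDomain(
        labels=labels,
        spacing=dx,
        origin=np.array([dx / 2.0, dx / 2.0, dx / 2.0]),
        meta={
            "fixture": "tube",
            "layout": {"port_diameter_mm": 2.0 * radius_mm},
            "radius_mm": radius_mm,
            "length_mm": length_mm,
        },
    )
    domain.require_percolation()
    return domain


def make_plane_channel(
    half_gap_mm: float = 0.25,
    length_mm: float = 5.0,
    width_mm: float = 4.0,
    spacing_mm: float = 0.05,
) -> VoxelDomain:
    """Plane-Poiseuille slot: a wide rectangular channel between two plates.

    The aspect ratio width/gap should be large (the default is 8) so the
    mid-channel profile approximates the infinite plane solution.
    """
    dx = spacing_mm
    n_gap = int(round(2 * half_gap_mm / dx))
    nx = int(round(length_mm / dx))
    ny = int(round(width_mm / dx)) + 2
    nz = n_gap + 2
    labels = np.full((nx, ny, nz), SOLID, dtype=np.int8)
    labels[:, 1:-1, 1:-1] = FLUID
    labels[0, 1:-1, 1:-1] = INLET
    labels[-1, 1:-1, 1:-1] = OUTLET
    domain = VoxelDomain(
        labels=labels,
        spacing=dx,
        origin=np.full(3, dx / 2.0),
        meta={
            "fixture": "plane_channel",
            "half_gap_mm": half_gap_mm,
            "length_mm": length_mm,
        },
    )
    domain.require_percolation()
    return domain


def make_cul_de_sac(
    spacing_mm: float = 0.05,
    channel_mm: tuple[float, float, float] = (8.0, 0.8, 0.8),
    pocket_mm: tuple[float, float] = (0.8, 2.0),
    neck_mm: tuple[float, float, float] = (0.5, 0.2, 0.4),
) -> VoxelDomain:
    """Straight square channel plus a closed side pocket behind a narrow neck.

    The pocket hangs off +y, connected to the channel only through the
    neck, and lies off the inlet-outlet path: it fills with fluid but
    carries essentially no through-flow, so its voxels are a ground-truth
    dead zone (recorded in ``meta['pocket_index_box']``, neck excluded).
    The pocket is deep (along y) but short along the flow axis, so its
    end faces do not skew the per-slice wall-pressure average by more
    than the axial pressure drop across the pocket span.
    """
    dx = spacing_mm
    cl, cw, ch = channel_mm
    pw, pd = pocket_mm  # width along x, depth along y
    nl, nd, nh = neck_mm  # neck length (x), depth (y), height (z)
    if not nd > 0 or nl <= 0 or nh <= 0:
        raise ValueError("neck dimensions must be positive")
    if pw > cl or nl > pw:
        raise ValueError("pocket/neck must fit along the channel")

    n_cl = int(round(cl / dx))
    n_cw = int(round(cw / dx))
    n_ch = int(round(ch / dx))
    n_pw = int(round(pw / dx))
    n_pd = int(round(pd / dx))
    n_nl = int(round(nl / dx))
    n_nd = int(round(nd / dx))
    n_nh = int(round(nh / dx))

    nx = n_cl
    ny = 1 + n_cw + n_nd + n_pd + 1
    nz = 1 + n_ch + 1
    labels = np.full((nx, ny, nz), SOLID, dtype=np.int8)

    # through-channel
    labels[:, 1 : 1 + n_cw, 1 : 1 + n_ch] = FLUID
    # neck, centred on the pocket along x and on the channel height along z
    p0 = (n_cl - n_pw) // 2
    if p0 <= 0:
        raise ValueError("pocket overlaps the ports")
    nck0 = p0 + (n_pw - n_nl) // 2
    k0 = 1 + (n_ch - n_nh) // 2
    labels[nck0 : nck0 + n_nl, 1 + n_cw : 1 + n_cw + n_nd, k0 : k0 + n_nh] = FLUID
    # pocket
    j_p = 1 + n_cw + n_nd
    labels[p0 : p0 + n_pw, j_p : j_p + n_pd, 1 : 1 + n_ch] = FLUID

    # port caps on the channel ends
    labels[0, 1 : 1 + n_cw, 1 : 1 + n_ch] = INLET
    labels[-1, 1 : 1 + n_cw, 1 : 1 + n_ch] = OUTLET

    domain = VoxelDomain(
        labels=labels,
        spacing=dx,
        origin=np.array([dx / 2.0, -dx / 2.0, -dx / 2.0]),
        meta={
            "fixture": "cul_de_sac",
            "pocket_index_box": [
                [p0, p0 + n_pw],
                [j_p, j_p + n_pd],
                [1, 1 + n_ch],
            ],
            "channel_mm": list(channel_mm),
        },
    )
    domain.require_percolation()
    return domain


def pocket_mask(domain: VoxelDomain) -> np.ndarray:
    """Ground-truth dead-zone mask of a cul-de-sac fixture."""
    box = domain.meta.get("pocket_index_box")
    if box is None:
        raise ValueError("domain records no pocket (not a cul-de-sac fixture?)")
    mask = np.zeros(domain.shape, dtype=bool)
    (i0, i1), (j0, j1), (k0, k1) = box
    mask[i0:i1, j0:j1, k0:k1] = True
    return mask & (domain.labels == FLUID)


def make_tpms_block(
    wavelength_mm: float = 5.0,
    cells: int = 1,
    resolution: int = 64,
    spec: TPMSSpec | None = None,
) -> VoxelDomain:
    """Periodic TPMS block (no ports): ``cells`` periods per axis,
    ``resolution`` voxels per period, classified by the field sign at
    voxel centres.  Used for porosity oracles and symmetry checks."""
    spec = spec or TPMSSpec.p_surface(wavelength_mm)
    dx = wavelength_mm / resolution
    n = cells * resolution
    coords = (np.arange(n) + 0.5) * dx
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    values = evaluate_tpms(spec, np.stack([X, Y, Z], axis=-1))
    labels = np.where(spec.fluid_where(values), FLUID, SOLID).astype(np.int8)
    return VoxelDomain(
        labels=labels,
        spacing=dx,
        origin=np.full(3, dx / 2.0),
        meta={"fixture": "tpms_block", "wavelength_mm": wavelength_mm},
    )


def monte_carlo_porosity(
    spec: TPMSSpec,
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    n_points: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Independent porosity oracle: fraction of uniform random points whose
    field sign classifies as fluid."""
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [rng.uniform(lo, hi, n_points) for (lo, hi) in bounds]
    )
    values = evaluate_tpms(spec, pts)
    return float(np.count_nonzero(spec.fluid_where(values)) / n_points)


def make_scaled_slab(
    scale: float = 0.25,
    wavelength_mm: float = 1.25,
    spacing_mm: float = 0.11,
    spec: TPMSSpec | None = None,
) -> VoxelDomain:
    """Desk-scale analogue of the vascular-like scaffold slab.

    Preserves the 66:30:10 aspect ratio and the port/width ratio
    3.08/30; at the default quarter scale the slab is 16.5 x 7.5 x 2.5 mm
    with 0.77 mm ports, small enough for a full pressure sweep on one
    CPU.  The default unit cell (1.25 mm, two cells across the slab
    height) keeps the pore flow in the low-Reynolds regime the full-size
    scaffold operates in, so the venous pressure drops of the study drive
    pore velocities the voxel grid can resolve.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    layout = ChannelLayout(
        slab_length=66.0 * scale,
        slab_width=30.0 * scale,
        slab_height=10.0 * scale,
        port_diameter=3.08 * scale,
        port_length=2.0 * scale,
    )
    spec = spec or TPMSSpec.p_surface(wavelength_mm)
    domain = build_domain(spec, layout, spacing_mm)
    domain.meta["fixture"] = "scaled_slab"
    domain.meta["scale"] = scale
    domain.meta["physical_dims_mm"] = [
        layout.slab_length,
        layout.slab_width,
        layout.slab_height,
    ]
    return domain


@dataclass
class FixtureSpec:
    """Declarative fixture description (name + keyword parameters)."""

    kind: str
    params: dict = dc_field(default_factory=dict)
    seed: int = 0  # used only by the Monte-Carlo porosity oracle


_MAKERS = {
    "tube": make_tube,
    "plane_channel": make_plane_channel,
    "cul_de_sac": make_cul_de_sac,
    "tpms_block": make_tpms_block,
    "scaled_slab": make_scaled_slab,
}


def make_fixture(spec: FixtureSpec) -> VoxelDomain:
    try:
        maker = _MAKERS[spec.kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {spec.kind!r}") from None
    return maker(**spec.params)
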