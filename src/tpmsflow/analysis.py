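"""Post-processing of a solved flow field into perfusion metrics.

Covers the quantities a perfusion study reports: wall-pressure statistics
and their axial gradient, cross-section velocity maxima, the realized
Reynolds number, and dead-zone detection (pore regions whose speed is a
negligible fraction of the mean, i.e. regions that would starve resident
cells of nutrient exchange).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .domain import FACE_STRUCTURE, FLUID, INLET, SOLID, VoxelDomain
from .flow import FlowField, FluidProperties, compute_reynolds, is_laminar

__all__ = [
    "PerfusionReport",
    "wall_pressure_stats",
    "section_velocity_max",
    "detect_dead_zones",
    "realized_reynolds",
    "analyze",
]

#: fraction of the mean pore speed below which a voxel counts as "almost
#: zero" flow; scale-free across pressure settings
DEAD_REL_THRESHOLD: float = 0.01
MIN_COMPONENT_VOXELS: int = 8


class UnconvergedFieldError(ValueError):
    """Dead zones are indistinguishable from non-convergence artefacts."""


def wall_mask(domain: VoxelDomain) -> np.ndarray:
    """FLUID voxels face-adjacent to SOLID (the voxel notion of "wall")."""
    solid = domain.labels == SOLID
    near_solid = ndimage.binary_dilation(solid, structure=FACE_STRUCTURE)
    return domain.fluid_mask & near_solid


def wall_pressure_stats(
    field: FlowField, domain: VoxelDomain, axis: int = 0
) -> tuple[float, float, np.ndarray]:
    """Max and mean wall pressure plus the mean-per-axial-slice profile.

    Wall voxels are fluid voxels touching the scaffold; if the domain has
    no solid at all (an open box) the statistics fall back to all fluid
    voxels with a warning.  The profile is reported over the slices that
    contain wall voxels, ordered along ``axis``.
    """
    mask = wall_mask(domain)
    if not mask.any():
        warnings.warn(
            "domain has no wall voxels; statistics taken over all fluid voxels",
            stacklevel=2,
        )
        mask = domain.fluid_mask
    p = field.pressure[mask]
    p_max = float(np.nanmax(p))
    p_mean = float(np.nanmean(p))

    moved = np.moveaxis(mask, axis, 0)
    pressure = np.moveaxis(field.pressure, axis, 0)
    profile = np.array(
        [
            float(np.nanmean(pressure[i][moved[i]]))
            for i in range(moved.shape[0])
            if moved[i].any()
        ]
    )
    return p_max, p_mean, profile


def section_velocity_max(
    field: FlowField, domain: VoxelDomain, index: int, axis: int = 0
) -> float:
    """Maximum speed over the fluid voxels of one cross-section."""
    labels = np.moveaxis(domain.labels, axis, 0)
    if not 0 <= index < labels.shape[0]:
        raise ValueError("section index outside the domain")
    section = labels[index]
    fluid = (section == FLUID) | (section >= 3)  # ports count as open section
    if not fluid.any():
        raise ValueError(f"section {index} has no fluid voxels")
    speed = np.moveaxis(field.speed(), axis, 0)[index]
    return float(speed[fluid].max())


def port_section_max(field: FlowField, domain: VoxelDomain, which: int = INLET) -> float:
    """Section maximum at a port's mid-plane (the inlet/outlet cross-section)."""
    cells = np.argwhere(domain.labels == which)
    if cells.size == 0:
        raise ValueError("domain has no such port")
    normal = domain.port_normal(which)
    axis = int(np.argmax(np.abs(normal)))
    # mid-plane of the port tube: halfway between the cap and the slab
    port_mask = np.moveaxis(domain.active_mask, axis, 0)
    cap = int(cells[0, axis])
    step = int(np.sign(normal[axis]))
    box = domain.meta.get("slab_index_box")
    if box is not None:
        slab_lo, slab_hi = box[axis]
        face = slab_lo if step > 0 else slab_hi - 1
        index = (cap + face) // 2
    else:
        index = cap + step
    return section_velocity_max(field, domain, index, axis=axis)


def detect_dead_zones(
    field: FlowField,
    domain: VoxelDomain,
    dead_rel_threshold: float = DEAD_REL_THRESHOLD,
    min_component_voxels: int = MIN_COMPONENT_VOXELS,
) -> tuple[float, np.ndarray]:
    """Identify stagnant pore regions.

    A fluid voxel is dead iff its speed is below ``dead_rel_threshold``
    times the mean fluid speed.  Dead voxels are grouped into
    face-connected components; components smaller than
    ``min_component_voxels`` are discarded as numerical noise.  Returns
    the dead fraction (dead voxels / fluid voxels) and the component
    label array (0 = not dead).
    """
    if not field.converged:
        raise UnconvergedFieldError(
            "refusing to detect dead zones on an unconverged field"
        )
    fluid = domain.fluid_mask
    n_fluid = int(fluid.sum())
    if n_fluid == 0:
        raise ValueError("domain has no fluid voxels")
    speed = field.speed()
    theta = dead_rel_threshold * float(speed[fluid].mean())
    dead = fluid & (speed < theta)
    comp, n = ndimage.label(dead, structure=FACE_STRUCTURE)
    if n:
        counts = np.bincount(comp.ravel())
        small = np.nonzero(counts < min_component_voxels)[0]
        comp[np.isin(comp, small[small > 0])] = 0
        # renumber surviving components contiguously
        survivors = np.unique(comp)
        remap = np.zeros(counts.size, dtype=comp.dtype)
        remap[survivors] = np.arange(len(survivors))
        comp = remap[comp]
    fraction = float(np.count_nonzero(comp) / n_fluid)
    return fraction, comp


def realized_reynolds(
    field: FlowField,
    domain: VoxelDomain,
    fluid: FluidProperties,
    diameter: float | None = None,
) -> float:
    """Reynolds number of the realized flow, from the mean inlet-port speed.

    ``diameter`` is in metres; when omitted it is taken from the recorded
    port diameter, falling back to the equivalent diameter of the inlet
    cap area.
    """
    inlet = domain.labels == INLET
    if not inlet.any():
        raise ValueError("domain has no inlet")
    v_b = float(field.speed()[inlet].mean())
    if v_b == 0.0:
        warnings.warn("zero inlet speed: blocked channel?", stacklevel=2)
        return 0.0
    if diameter is None:
        d_mm = domain.meta.get("layout", {}).get("port_diameter_mm")
        if d_mm is not None:
            diameter = d_mm * 1e-3
        else:
            area = inlet.sum() * (domain.spacing * 1e-3) ** 2
            diameter = float(np.sqrt(4.0 * area / np.pi))
    re = compute_reynolds(v_b, diameter, fluid)
    if not is_laminar(re):
        warnings.warn(f"realized Re {re:.0f} is not laminar", stacklevel=2)
    return re


@dataclass
class PerfusionReport:
    """Summary of one converged perfusion run."""

    max_wall_pressure: float  # Pa
    mean_wall_pressure: float  # Pa
    axial_pressure_profile: np.ndarray  # Pa per axial slice
    max_inlet_section_speed: float  # m/s
    max_outlet_section_speed: float  # m/s
    realized_Re: float
    dead_zone_fraction: float
    dead_zone_labels: np.ndarray = dc_field(repr=False)
    inlet_pressure: float = float("nan")  # Pa, for run comparison
    outlet_pressure: float = float("nan")
    porosity: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.dead_zone_fraction <= 1.0:
            raise ValueError("dead_zone_fraction must lie in [0, 1]")
        if self.max_wall_pressure < self.mean_wall_pressure - 1e-9:
            raise ValueError("max wall pressure below the mean")

    def to_dict(self) -> dict:
        return {
            "max_wall_pressure_pa": self.max_wall_pressure,
            "mean_wall_pressure_pa": self.mean_wall_pressure,
            "axial_pressure_profile_pa": [float(v) for v in self.axial_pressure_profile],
            "max_inlet_section_speed_mps": self.max_inlet_section_speed,
            "max_outlet_section_speed_mps": self.max_outlet_section_speed,
            "realized_Re": self.realized_Re,
            "dead_zone_fraction": self.dead_zone_fraction,
            "inlet_pressure_pa": self.inlet_pressure,
            "outlet_pressure_pa": self.outlet_pressure,
            "porosity": self.porosity,
        }


def analyze(
    field: FlowField,
    domain: VoxelDomain,
    fluid: FluidProperties | None = None,
    dead_rel_threshold: float = DEAD_REL_THRESHOLD,
    min_component_voxels: int = MIN_COMPONENT_VOXELS,
) -> PerfusionReport:
    """Build the full perfusion report for a converged run."""
    from .domain import OUTLET
    from .geometry import measure_porosity

    fluid_props = fluid or (field.fluid or FluidProperties())
    p_max, p_mean, profile = wall_pressure_stats(field, domain)
    fraction, labels = detect_dead_zones(
        field, domain, dead_rel_threshold, min_component_voxels
    )
    try:
        porosity = measure_porosity(domain)
    except ValueError:
        porosity = float("nan")
    return PerfusionReport(
        max_wall_pressure=p_max,
        mean_wall_pressure=p_mean,
        axial_pressure_profile=profile,
        max_inlet_section_speed=port_section_max(field, domain, INLET),
        max_outlet_section_speed=port_section_max(field, domain, OUTLET),
        realized_Re=realized_reynolds(field, domain, fluid_props),
        dead_zone_fraction=fraction,
        dead_zone_labels=labels,
        inlet_pressure=field.bc.inlet_pressure if field.bc else float("nan"),
        outlet_pressure=field.bc.outlet_pressure if field.bc else float("nan"),
        porosity=porosity,
    )
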