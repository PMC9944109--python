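"""Dead-zone-driven scaffold pruning and before/after comparison.

The optimization step removes scaffold regions that the flow does not
perfuse — either manually chosen axis-aligned corner boxes (the procedure
used to trim the top-left / bottom-right corners of the vascular-like
channel model) or the components the dead-zone detector flags — then the
domain is re-solved and the perfusion reports compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .domain import (
    EXTERIOR,
    FACE_STRUCTURE,
    FLUID,
    INLET,
    OUTLET,
    SOLID,
    NoPercolationError,
    VoxelDomain,
    slab_box,
)
from .analysis import PerfusionReport

__all__ = ["PruningPlan", "RunComparison", "prune", "compare_runs"]

#: dead_zone_fraction below which a pruned model counts as fully perfused
FULL_PERFUSION_THRESHOLD: float = 0.005


@dataclass
class PruningPlan:
    """What to remove from the model.

    ``boxes_mm`` are axis-aligned boxes ``((x0, x1), (y0, y1), (z0, z1))``
    in physical mm; ``component_ids`` select components of
    ``dead_labels`` (the array produced by the dead-zone detector), each
    dilated by ``margin`` voxels so the stagnant boundary skin of a
    pocket is removed with it.  Removed voxels become EXTERIOR (material
    cut from the model footprint) unless ``backfill='solid'``.
    """

    boxes_mm: list = dc_field(default_factory=list)
    component_ids: list = dc_field(default_factory=list)
    dead_labels: np.ndarray | None = None
    margin: int = 2
    backfill: str = "exterior"

    def __post_init__(self) -> None:
        if self.backfill not in ("exterior", "solid"):
            raise ValueError("backfill must be 'exterior' or 'solid'")
        if self.component_ids and self.dead_labels is None:
            raise ValueError("component_ids require dead_labels")

    @classmethod
    def corner_boxes(
        cls,
        length: float,
        width: float,
        height: float,
        frac_x: float = 0.25,
        frac_y: float = 0.4,
    ) -> "PruningPlan":
        """Default corner trim: top-left and bottom-right boxes over the full height."""
        return cls(
            boxes_mm=[
                ((0.0, frac_x * length), ((1 - frac_y) * width, width), (0.0, height)),
                ((length * (1 - frac_x), length), (0.0, frac_y * width), (0.0, height)),
            ]
        )


def _removal_mask(domain: VoxelDomain, plan: PruningPlan) -> np.ndarray:
    mask = np.zeros(domain.shape, dtype=bool)
    if plan.boxes_mm:
        xs, ys, zs = domain.axes()
        for (x0, x1), (y0, y1), (z0, z1) in plan.boxes_mm:
            mask |= (
                ((xs >= x0) & (xs <= x1))[:, None, None]
                & ((ys >= y0) & (ys <= y1))[None, :, None]
                & ((zs >= z0) & (zs <= z1))[None, None, :]
            )
    if plan.component_ids:
        comp = np.isin(plan.dead_labels, np.asarray(plan.component_ids))
        if plan.margin > 0:
            comp = ndimage.binary_dilation(
                comp, structure=FACE_STRUCTURE, iterations=plan.margin
            )
        mask |= comp
    # pruning touches only the scaffold slab, never the ports
    slab = np.zeros(domain.shape, dtype=bool)
    slab[slab_box(domain)] = True
    return mask & slab


def prune(domain: VoxelDomain, plan: PruningPlan) -> VoxelDomain:
    """Remove the planned regions and return a new domain.

    Refuses plans that intersect a port cap or sever the inlet-outlet
    connection; an empty plan returns an identical copy.
    """
    mask = _removal_mask(domain, plan)
    ports = (domain.labels == INLET) | (domain.labels == OUTLET)
    if (mask & ports).any():
        raise ValueError("pruning plan intersects a port")

    new = domain.copy()
    fill = EXTERIOR if plan.backfill == "exterior" else SOLID
    removable = mask & ((domain.labels == FLUID) | (domain.labels == SOLID))
    new.labels[removable] = fill

    if not new.percolates():
        raise NoPercolationError(
            "pruning plan severs the inlet-outlet connection; "
            f"it would remove {int(removable.sum())} voxels"
        )
    from .geometry import measure_porosity

    new.meta["pruned_voxels"] = int(removable.sum())
    new.meta["porosity_after_prune"] = measure_porosity(new)
    return new


@dataclass(frozen=True)
class RunComparison:
    """Deltas (after - before) of the headline perfusion metrics."""

    delta_dead_zone_fraction: float
    delta_max_inlet_section_speed: float
    delta_max_outlet_section_speed: float
    delta_max_wall_pressure: float
    fully_perfused: bool


def compare_runs(
    before: PerfusionReport,
    after: PerfusionReport,
    full_perfusion_threshold: float = FULL_PERFUSION_THRESHOLD,
) -> RunComparison:
    """Compare perfusion reports taken at identical boundary conditions."""
    same_bc = np.isclose(before.inlet_pressure, after.inlet_pressure) and np.isclose(
        before.outlet_pressure, after.outlet_pressure
    )
    if not same_bc:
        raise ValueError("reports were produced under different boundary conditions")
    return RunComparison(
        delta_dead_zone_fraction=after.dead_zone_fraction - before.dead_zone_fraction,
        delta_max_inlet_section_speed=(
            after.max_inlet_section_speed - before.max_inlet_section_speed
        ),
        delta_max_outlet_section_speed=(
            after.max_outlet_section_speed - before.max_outlet_section_speed
        ),
        delta_max_wall_pressure=after.max_wall_pressure - before.max_wall_pressure,
        fully_perfused=after.dead_zone_fraction < full_perfusion_threshold,
    )
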