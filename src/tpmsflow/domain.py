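"""Voxelized flow-channel domains.

A :class:`VoxelDomain` is a regular isotropic 3D grid in which every voxel
carries one label: ``EXTERIOR`` (outside the model footprint), ``SOLID``
(scaffold material), ``FLUID`` (pore space), or ``INLET``/``OUTLET`` (the
pressure-port caps).  Physical coordinates are millimetres; the centre of
voxel ``(i, j, k)`` sits at ``origin + spacing * (i, j, k)``.  By convention
``x`` (axis 0) is the perfusion axis, but nothing downstream assumes it:
ports are located by their labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import ndimage

EXTERIOR: int = 0
SOLID: int = 1
FLUID: int = 2
INLET: int = 3
OUTLET: int = 4

LABEL_NAMES = {
    EXTERIOR: "exterior",
    SOLID: "solid",
    FLUID: "fluid",
    INLET: "inlet",
    OUTLET: "outlet",
}

#: 6-connectivity structuring element (face adjacency), shared by the
#: percolation check, dead-zone labelling and the solver's wall stencil.
FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)

_AXIS_NEIGHBOURS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


class NoPercolationError(ValueError):
    """Raised when no face-connected fluid path joins inlet to outlet."""


@dataclass
class VoxelDomain:
    """Labelled voxel grid with physical spacing.

    Parameters
    ----------
    labels
        ``int8`` array of shape ``(nx, ny, nz)`` holding the label codes.
    spacing
        Isotropic voxel pitch in mm.
    origin
        Physical position (mm) of the centre of voxel ``(0, 0, 0)``.
    meta
        Free-form, JSON-serialisable provenance (layout parameters, the
        slab index box used for porosity, fixture ground truth, ...).
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    # -- basic views ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.labels == FLUID

    @property
    def active_mask(self) -> np.ndarray:
        """Voxels the flow solver evolves: fluid plus both port caps."""
        return (self.labels == FLUID) | (self.labels == INLET) | (self.labels == OUTLET)

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of voxel centres along each axis."""
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.shape[a]) for a in range(3)
        )

    # -- connectivity --------------------------------------------------

    def connected_labels(self) -> tuple[np.ndarray, int]:
        """Face-connected components of the active (fluid+port) set."""
        return ndimage.label(self.active_mask, structure=FACE_STRUCTURE)

    def percolates(self) -> bool:
        """True iff some fluid component touches both an INLET and an OUTLET voxel."""
        if self.count(INLET) == 0 or self.count(OUTLET) == 0:
            return False
        comp, n = self.connected_labels()
        if n == 0:
            return False
        inlet_ids = np.unique(comp[self.labels == INLET])
        outlet_ids = np.unique(comp[self.labels == OUTLET])
        return bool(np.intersect1d(inlet_ids, outlet_ids).size > 0)

    def require_percolation(self) -> None:
        if not self.percolates():
            raise NoPercolationError(
                "no percolating fluid channel connects INLET to OUTLET"
            )

    def port_normal(self, label: int) -> np.ndarray:
        """Inward unit normal of a port cap, inferred from adjacency.

        The cap is assumed planar: the inward direction is the face
        direction in which most port voxels see a FLUID neighbour.
        """
        cells = np.argwhere(self.labels == label)
        if cells.size == 0:
            raise ValueError(f"domain has no {LABEL_NAMES.get(label, label)} voxels")
        best, best_count = None, -1
        for d in _AXIS_NEIGHBOURS:
            nbr = cells + d
            ok = np.all((nbr >= 0) & (nbr < np.array(self.shape)), axis=1)
            count = int(
                np.count_nonzero(
                    self.labels[tuple(nbr[ok].T)] == FLUID
                )
            )
            if count > best_count:
                best, best_count = d, count
        if best_count <= 0:
            raise ValueError(
                f"{LABEL_NAMES.get(label, label)} cap has no adjacent FLUID voxel"
            )
        return np.asarray(best, dtype=float)

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        """Write the domain to an NPZ container (labels, spacing, origin, meta)."""
        import json

        np.savez_compressed(
            path,
            labels=self.labels,
            spacing=np.float64(self.spacing),
            origin=self.origin,
            meta=np.frombuffer(json.dumps(self.meta, sort_keys=True).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "VoxelDomain":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode()) if "meta" in data else {}
            return cls(
                labels=data["labels"],
                spacing=float(data["spacing"]),
                origin=data["origin"],
                meta=meta,
            )

    def copy(self) -> "VoxelDomain":
        return VoxelDomain(
            labels=self.labels.copy(),
            spacing=self.spacing,
            origin=self.origin.copy(),
            meta=dict(self.meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelDomain):
            return NotImplemented
        return (
            self.labels.shape == other.labels.shape
            and np.array_equal(self.labels, other.labels)
            and self.spacing == other.spacing
            and np.allclose(self.origin, other.origin)
        )


def slab_box(domain: VoxelDomain) -> tuple[slice, slice, slice]:
    """Index slices of the scaffold slab region.

    Falls back to the whole grid when the domain records no slab box
    (benchmark fixtures without ports/slab distinction).
    """
    box = domain.meta.get("slab_index_box")
    if box is None:
        return (slice(None), slice(None), slice(None))
    (i0, i1), (j0, j1), (k0, k1) = box
    return (slice(i0, i1), slice(j0, j1), slice(k0, k1))


def iter_port_cells(domain: VoxelDomain, label: int) -> Iterator[tuple[int, int, int]]:
    for idx in np.argwhere(domain.labels == label):
        yield tuple(int(v) for v in idx)
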