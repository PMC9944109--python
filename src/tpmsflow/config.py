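"""Structured-file configuration of a perfusion study.

A YAML file with ``tpms``, ``layout``, ``grid``, ``fluid``, ``bc`` and
``solver`` blocks maps onto the corresponding dataclasses, e.g.::

    tpms:    {preset: p_surface, wavelength_mm: 5.0, mode: network,
              fluid_sign: nonnegative}
    layout:  {length_mm: 66.0, width_mm: 30.0, height_mm: 10.0,
              port_diameter_mm: 3.08, port_length_mm: 2.0}
    grid:    {spacing_mm: 0.5}
    fluid:   {density: 1060.0, viscosity: 0.005}
    bc:      {inlet_mmHg: 12.0, outlet_mmHg: 11.0}
    solver:  {max_iterations: 60000, convergence_tol: 1.0e-6}

Only the blocks present are parsed; missing entries take the package
defaults.
"""

from __future__ import annotations

import yaml

from .flow import BoundaryConditions, FluidProperties, SolverSettings
from .geometry import ChannelLayout, TPMSSpec


def load_config(path) -> dict:
    """Parse a YAML study file into dataclass instances.

    Returns a dict with keys ``tpms``, ``layout``, ``spacing_mm``,
    ``fluid``, ``bc``, ``solver`` (present only when configured).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}

    if "tpms" in raw:
        blk = dict(raw["tpms"])
        preset = blk.pop("preset", "p_surface")
        if preset != "p_surface":
            raise ValueError(f"unknown TPMS preset {preset!r}")
        spec = TPMSSpec.p_surface(
            wavelength=blk.pop("wavelength_mm", 5.0),
            mode=blk.pop("mode", "network"),
            fluid_sign=blk.pop("fluid_sign", "nonnegative"),
            half_thickness=blk.pop("half_thickness", 0.3),
        )
        level = blk.pop("level_constant", None)
        if level is not None:
            spec.level_constant = level
        if blk:
            raise ValueError(f"unknown tpms keys: {sorted(blk)}")
        out["tpms"] = spec

    if "layout" in raw:
        blk = raw["layout"]
        out["layout"] = ChannelLayout(
            slab_length=blk.get("length_mm", 66.0),
            slab_width=blk.get("width_mm", 30.0),
            slab_height=blk.get("height_mm", 10.0),
            port_diameter=blk.get("port_diameter_mm", 3.08),
            port_length=blk.get("port_length_mm", 2.0),
        )

    if "grid" in raw:
        out["spacing_mm"] = float(raw["grid"]["spacing_mm"])

    if "fluid" in raw:
        blk = raw["fluid"]
        out["fluid"] = FluidProperties(
            density=blk.get("density", 1060.0),
            dynamic_viscosity=blk.get("viscosity", 0.005),
        )

    if "bc" in raw:
        blk = raw["bc"]
        out["bc"] = BoundaryConditions.from_mmhg(
            blk["inlet_mmHg"], blk["outlet_mmHg"]
        )

    if "solver" in raw:
        out["solver"] = SolverSettings(**raw["solver"])

    return out
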