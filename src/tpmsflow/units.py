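"""Pressure unit handling.

Perfusion pressures are quoted clinically in mmHg while the solver works
in Pa; the exact conversion factor 1 mmHg = 133.322 Pa is used so that
round trips are identity to machine precision.
"""

from __future__ import annotations

import math

PA_PER_MMHG: float = 133.322

_UNITS = ("Pa", "mmHg")


def pressure_convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between Pa and mmHg."""
    if from_unit not in _UNITS:
        raise ValueError(f"unknown pressure unit {from_unit!r}")
    if to_unit not in _UNITS:
        raise ValueError(f"unknown pressure unit {to_unit!r}")
    if not math.isfinite(value):
        raise ValueError("pressure value must be finite")
    if from_unit == to_unit:
        return float(value)
    if from_unit == "mmHg":
        return float(value) * PA_PER_MMHG
    return float(value) / PA_PER_MMHG


def mmhg_to_pa(value: float) -> float:
    return pressure_convert(value, "mmHg", "Pa")


def pa_to_mmhg(value: float) -> float:
    return pressure_convert(value, "Pa", "mmHg")
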