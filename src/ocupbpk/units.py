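"""Unit handling.

The model works in a single internal unit system: amounts in µg, volumes in
mL, time in hours, particle radii in µm.  All user-facing parameters keep the
units they are conventionally reported in (permeabilities in cm/s, drainage
rates in min⁻¹, tear flows in µL/min, ...) and are converted on ingestion.

``parse_quantity`` lets configuration files attach a unit suffix to a number
("50 uL", "0.1 1/min"); the value is converted to the canonical unit of the
field it is assigned to.
"""

from __future__ import annotations

import re

# conversions to internal units
CM_PER_S_TO_CM_PER_H = 3600.0
PER_S_TO_PER_H = 3600.0
PER_MIN_TO_PER_H = 60.0
MIN_TO_H = 1.0 / 60.0
UL_TO_ML = 1e-3
MG_PER_ML_TO_UG_PER_ML = 1e3
G_PER_ML_TO_UG_PER_ML = 1e6
UM_TO_CM = 1e-4

#: factor taking ``unit`` to the canonical unit of its dimension
_TO_CANONICAL: dict[str, tuple[str, float]] = {
    # volume -> µL
    "uL": ("uL", 1.0),
    "µL": ("uL", 1.0),
    "mL": ("uL", 1e3),
    "L": ("uL", 1e6),
    # concentration / strength -> mg/mL
    "mg/mL": ("mg/mL", 1.0),
    "ug/mL": ("mg/mL", 1e-3),
    "µg/mL": ("mg/mL", 1e-3),
    "g/L": ("mg/mL", 1.0),
    # length -> µm
    "um": ("um", 1.0),
    "µm": ("um", 1.0),
    "nm": ("um", 1e-3),
    # velocity (permeability) -> cm/s
    "cm/s": ("cm/s", 1.0),
    "cm/h": ("cm/s", 1.0 / 3600.0),
    # first-order rate -> 1/min
    "1/min": ("1/min", 1.0),
    "min^-1": ("1/min", 1.0),
    "1/s": ("1/min", 60.0),
    "s^-1": ("1/min", 60.0),
    "1/h": ("1/min", 1.0 / 60.0),
    "h^-1": ("1/min", 1.0 / 60.0),
    # flow -> µL/min
    "uL/min": ("uL/min", 1.0),
    "µL/min": ("uL/min", 1.0),
    "mL/h": ("uL/min", 1e3 / 60.0),
    # time -> h
    "h": ("h", 1.0),
    "hr": ("h", 1.0),
    "min": ("h", MIN_TO_H),
    "s": ("h", 1.0 / 3600.0),
    # mass -> kg
    "kg": ("kg", 1.0),
    "g": ("kg", 1e-3),
}

#: canonical unit expected for each dimension name used by the config schema
CANONICAL = {
    "volume": "uL",
    "strength": "mg/mL",
    "length": "um",
    "permeability": "cm/s",
    "rate": "1/min",
    "flow": "uL/min",
    "time": "h",
    "mass": "kg",
}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(.*?)\s*$")


def parse_quantity(value, dimension: str) -> float:
    """Parse a bare number or a "number unit" string into the canonical unit.

    Bare numbers are assumed to already be in the canonical unit of
    ``dimension`` (e.g. µL for volumes, h for times).
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise TypeError(f"cannot parse quantity from {value!r}")
    m = _QTY_RE.match(value)
    if not m:
        raise ValueError(f"malformed quantity {value!r}")
    number, unit = float(m.group(1)), m.group(2)
    canonical = CANONICAL[dimension]
    if not unit:
        return number
    if unit not in _TO_CANONICAL:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    target, factor = _TO_CANONICAL[unit]
    if target != canonical:
        raise ValueError(
            f"unit {unit!r} is a {target} unit, expected a {canonical} unit"
        )
    return number * factor
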