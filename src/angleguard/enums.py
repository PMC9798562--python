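"""Shared categorical vocabularies (quadrants, angle classes, iris shapes)."""

from __future__ import annotations

from enum import Enum


class Quadrant(str, Enum):
    TEMPORAL = "temporal"
    NASAL = "nasal"
    SUPERIOR = "superior"
    INFERIOR = "inferior"


class AngleClass(str, Enum):
    """Preset-angle classification of one anterior-chamber-angle quadrant.

    *open*: the peripheral iris stays outside the preset wedge;
    *narrow*: some peripheral iris falls strictly inside the wedge;
    *closed*: iris and trabecular meshwork are apposed;
    *ungradable*: the scan could not be assessed.
    """

    OPEN = "open"
    NARROW = "narrow"
    CLOSED = "closed"
    UNGRADABLE = "ungradable"


class IrisConfiguration(str, Enum):
    FLAT = "flat"
    BOWING = "bowing"
    BOMBE = "bombe"
    THICK_PERIPHERAL = "thick_peripheral"
    MIXED = "mixed"


class Eye(str, Enum):
    OD = "OD"
    OS = "OS"


class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"


#: Decade age bands used for stratified prevalence reporting.
AGE_BANDS = ("40-49", "50-59", "60-69", "70+")


def age_band(age: float) -> str:
    """Map an age in years (>= 40) to its reporting band."""
    if age < 40:
        raise ValueError(f"age {age} outside the screened range (>= 40)")
    if age < 50:
        return "40-49"
    if age < 60:
        return "50-59"
    if age < 70:
        return "60-69"
    return "70+"
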