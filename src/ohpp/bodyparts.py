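"""The 14-part body vocabulary and the 28-flag protection schema.

Occupational Health Protection Profiles restrict activity per body part at
one of two protection levels: ``MN`` ("Must Not use", the more severe) or
``SN`` ("Should Not use"). Eight anatomical regions are tracked; six of them
are lateralised (left/right), the neck and trunk are not, giving 14 body
parts and, after splitting each part into an MN and an SN indicator, a fixed
28-column binary schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator


class Side(str, Enum):
    LEFT = "L"
    RIGHT = "R"
    NONE = ""


class ProtectionLevel(str, Enum):
    """MN = Must Not use (more severe); SN = Should Not use."""

    MN = "MN"
    SN = "SN"


#: regions without laterality
UNSIDED_REGIONS = ("neck", "trunk")
#: lateralised regions, canonical order
SIDED_REGIONS = ("shoulder", "elbow", "wrist", "fingers", "knee", "foot")
REGIONS = UNSIDED_REGIONS + SIDED_REGIONS


@dataclass(frozen=True, order=True)
class BodyPart:
    region: str
    side: Side = Side.NONE

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.region in UNSIDED_REGIONS and self.side is not Side.NONE:
            raise ValueError(f"{self.region} carries no laterality")
        if self.region in SIDED_REGIONS and self.side is Side.NONE:
            raise ValueError(f"{self.region} requires a side")

    @property
    def name(self) -> str:
        """Canonical column-style name, e.g. ``ShoulderL`` or ``Trunk``."""
        return self.region.capitalize() + self.side.value

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


def all_body_parts() -> tuple[BodyPart, ...]:
    """The 14 body parts in canonical column order."""

    def gen() -> Iterator[BodyPart]:
        for region in UNSIDED_REGIONS:
            yield BodyPart(region)
        for region in SIDED_REGIONS:
            yield BodyPart(region, Side.LEFT)
            yield BodyPart(region, Side.RIGHT)

    return tuple(gen())


BODY_PARTS: tuple[BodyPart, ...] = all_body_parts()
PART_NAMES: tuple[str, ...] = tuple(p.name for p in BODY_PARTS)

#: the ordered 28-flag schema: <Part>_MN, <Part>_SN per part
FLAG_COLUMNS: tuple[str, ...] = tuple(
    f"{p.name}_{lvl.value}" for p in BODY_PARTS for lvl in (ProtectionLevel.MN, ProtectionLevel.SN)
)

_BY_NAME = {p.name: p for p in BODY_PARTS}


def part_from_name(name: str) -> BodyPart:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ValueError(f"unknown body part name {name!r}") from None
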