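"""Hierarchical land-cover legend.

The map legend has two levels. Level 1 holds eight general land-cover
types (Built-up ... Cropland & Grassland). Level 2 refines two of them:
Wetland splits into marsh and exploited/unexploited peat bog, and
Cropland & Grassland splits into eight crop types plus grassland. The
final maps carry the 18 Level-2 codes 1..18; codes 1..6 are identical at
both levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

NODATA = 0  # label rasters use 0 as nodata so a byte band suffices

# Level-1 codes
L1_BUILTUP = 1
L1_BARELAND = 2
L1_WATER = 3
L1_SHRUBLAND = 4
L1_CONIFEROUS = 5
L1_BROADLEAF = 6
L1_WETLAND = 7
L1_CROP_GRASS = 8

LEVEL1_NAMES: dict[int, str] = {
    L1_BUILTUP: "Built-up",
    L1_BARELAND: "Bareland",
    L1_WATER: "Water",
    L1_SHRUBLAND: "Shrubland",
    L1_CONIFEROUS: "Coniferous forest",
    L1_BROADLEAF: "Broadleaf forest",
    L1_WETLAND: "Wetland",
    L1_CROP_GRASS: "Cropland and grassland",
}


@dataclass(frozen=True)
class LegendEntry:
    code: int
    name: str
    level: int  # 1 if the class is not subdivided, 2 if it is a refinement
    parent_level1_code: int


@dataclass(frozen=True)
class Legend:
    """The final (Level-2) legend: 18 contiguous codes with Level-1 parents."""

    entries: tuple[LegendEntry, ...]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if sorted(codes) != list(range(1, len(codes) + 1)):
            raise ValueError(f"legend codes must be contiguous 1..n, got {sorted(codes)}")
        for e in self.entries:
            if e.parent_level1_code not in LEVEL1_NAMES:
                raise ValueError(f"unknown Level-1 parent {e.parent_level1_code} for {e.name}")

    @property
    def codes(self) -> list[int]:
        return [e.code for e in self.entries]

    def name(self, code: int) -> str:
        for e in self.entries:
            if e.code == code:
                return e.name
        raise KeyError(code)

    def parent(self, code: int) -> int:
        for e in self.entries:
            if e.code == code:
                return e.parent_level1_code
        raise KeyError(code)

    def children(self, level1_code: int) -> list[int]:
        return [e.code for e in self.entries if e.parent_level1_code == level1_code]

    def validate_codes(self, values) -> list[int]:
        """Return sorted offending codes (not in legend and not nodata)."""
        import numpy as np

        uniq = np.unique(np.asarray(values))
        valid = set(self.codes) | {NODATA}
        return sorted(int(v) for v in uniq if int(v) not in valid)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = [
            {
                "code": e.code,
                "name": e.name,
                "level": e.level,
                "parent_level1_code": e.parent_level1_code,
                "parent_level1_name": LEVEL1_NAMES[e.parent_level1_code],
            }
            for e in self.entries
        ]
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Legend":
        payload = json.loads(Path(path).read_text())
        return cls(
            tuple(
                LegendEntry(p["code"], p["name"], p["level"], p["parent_level1_code"])
                for p in payload
            )
        )


def default_legend() -> Legend:
    """The 18-class legend of the annual maps."""
    e = LegendEntry
    return Legend(
        (
            e(1, "Built-up", 1, L1_BUILTUP),
            e(2, "Bareland", 1, L1_BARELAND),
            e(3, "Water", 1, L1_WATER),
            e(4, "Shrubland", 1, L1_SHRUBLAND),
            e(5, "Coniferous forest", 1, L1_CONIFEROUS),
            e(6, "Broadleaf forest", 1, L1_BROADLEAF),
            e(7, "Wetland marsh", 2, L1_WETLAND),
            e(8, "Exploited peat bog", 2, L1_WETLAND),
            e(9, "Unexploited peat bog", 2, L1_WETLAND),
            e(10, "Wheat", 2, L1_CROP_GRASS),
            e(11, "Barley", 2, L1_CROP_GRASS),
            e(12, "Rye", 2, L1_CROP_GRASS),
            e(13, "Oats", 2, L1_CROP_GRASS),
            e(14, "Maize", 2, L1_CROP_GRASS),
            e(15, "Seed crops", 2, L1_CROP_GRASS),
            e(16, "Root crops", 2, L1_CROP_GRASS),
            e(17, "Pulses, vegetables", 2, L1_CROP_GRASS),
            e(18, "Grassland", 2, L1_CROP_GRASS),
        )
    )


DEFAULT_LEGEND = default_legend()

# final code -> Level-1 code, for aggregating Level-2 maps
LEVEL2_TO_LEVEL1: dict[int, int] = {e.code: e.parent_level1_code for e in DEFAULT_LEGEND.entries}

WETLAND_CODES = tuple(DEFAULT_LEGEND.children(L1_WETLAND))  # (7, 8, 9)
CROP_GRASS_CODES = tuple(DEFAULT_LEGEND.children(L1_CROP_GRASS))  # (10, ..., 18)
CROP_CODES = tuple(c for c in CROP_GRASS_CODES if c != 18)  # rotating arable classes
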