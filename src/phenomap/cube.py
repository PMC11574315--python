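"""Multi-year label cube: one class-code grid per year on a shared grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geoio import DEFAULT_CRS, GeoTransform
from .legend import NODATA


@dataclass
class LabelCube:
    """Annual class-code maps stacked over an ordered list of years."""

    years: list[int]
    data: np.ndarray  # (n_years, rows, cols) integer codes
    transform: GeoTransform = field(default_factory=lambda: GeoTransform(0.0, 0.0, 30.0))
    crs: str = DEFAULT_CRS
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.years):
            raise ValueError("data must be (n_years, rows, cols) matching `years`")
        if sorted(self.years) != list(self.years):
            raise ValueError("years must be ascending")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def year_index(self, year: int) -> int:
        return self.years.index(year)

    def grid(self, year: int) -> np.ndarray:
        return self.data[self.year_index(year)]

    def copy(self) -> "LabelCube":
        return LabelCube(list(self.years), self.data.copy(), self.transform, self.crs,
                         self.nodata)

    def class_pixel_counts(self, code: int) -> dict[int, int]:
        return {y: int((self.data[i] == code).sum()) for i, y in enumerate(self.years)}
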