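"""Weekly temporal encoding of irregular observation series.

An annual, irregularly sampled reflectance time series is turned into a
fixed 52-week x 9-band matrix: all clear observations falling in the
same calendar week are averaged into that week's slot, and weeks with no
clear observation hold exactly 0. The zero-filled representation neither
compresses nor interpolates the series, which is what makes a model
trained on dense years transferable to sparse ones. Nine bands are
encoded: six reflectance bands (red, green, blue, NIR, SWIR1, SWIR2) and
three indices (NDVI, NDWI, SAVI) derived from them, 52 x 9 = 468 values
per sample.

Two training-time augmentations mimic the gap between dense training
years and sparse historical years: random observation selection thins
the series, and random day shifting moves the whole season by a common
offset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

N_WEEKS = 52
BAND_NAMES = ("red", "green", "blue", "nir", "swir1", "swir2", "ndvi", "ndwi", "savi")
N_BANDS = len(BAND_NAMES)
SAVI_L = 0.5  # canonical soil-adjustment factor


@dataclass(frozen=True)
class ObservationSeries:
    """One pixel-year of dated observations.

    `values` holds either the 6 reflectance bands or the full 9 bands
    (reflectances + indices), one row per acquisition date.
    """

    year: int
    doy: np.ndarray  # (n,) int, strictly increasing, in [1, 366]
    values: np.ndarray  # (n, 6) or (n, 9) float
    clear: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        doy = np.asarray(self.doy)
        if doy.size and (np.any(np.diff(doy) <= 0) or doy.min() < 1 or doy.max() > 366):
            raise ValueError("DOYs must be strictly increasing within [1, 366]")
        if np.asarray(self.values).shape[0] != doy.size:
            raise ValueError("values and doy length mismatch")

    @property
    def n_obs(self) -> int:
        return int(np.asarray(self.doy).size)

    def clear_only(self) -> "ObservationSeries":
        m = np.asarray(self.clear, bool)
        return replace(
            self, doy=np.asarray(self.doy)[m], values=np.asarray(self.values)[m],
            clear=np.ones(int(m.sum()), bool),
        )


@dataclass(frozen=True)
class EncodedSample:
    matrix: np.ndarray  # (52, 9)
    year: int
    label: int | None = None


def compute_indices(red, green, blue, nir, swir1, swir2):
    """NDVI, NDWI (green/NIR form) and SAVI from reflectance fractions.

    Zero denominators yield an index of 0 (flagged via the returned mask
    in `compute_indices_flagged`).
    """
    ndvi, ndwi, savi = compute_indices_flagged(red, green, blue, nir, swir1, swir2)[0]
    return ndvi, ndwi, savi


def compute_indices_flagged(red, green, blue, nir, swir1, swir2):
    red, green, nir = (np.asarray(a, float) for a in (red, green, nir))
    d1 = nir + red
    d2 = green + nir
    d3 = nir + red + SAVI_L
    flag = (d1 == 0) | (d2 == 0) | (d3 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(d1 == 0, 0.0, (nir - red) / np.where(d1 == 0, 1, d1))
        ndwi = np.where(d2 == 0, 0.0, (green - nir) / np.where(d2 == 0, 1, d2))
        savi = np.where(d3 == 0, 0.0, (nir - red) * (1 + SAVI_L) / np.where(d3 == 0, 1, d3))
    return (ndvi, ndwi, savi), flag


def with_indices(values: np.ndarray) -> np.ndarray:
    """Append NDVI/NDWI/SAVI columns to a (n, 6) reflectance array."""
    values = np.asarray(values, float)
    if values.ndim != 2 or values.shape[1] not in (6, 9):
        raise ValueError("expected (n, 6) reflectances or (n, 9) full values")
    if values.shape[1] == 9:
        return values
    r, g, b, n, s1, s2 = values.T
    ndvi, ndwi, savi = compute_indices(r, g, b, n, s1, s2)
    return np.column_stack([values, ndvi, ndwi, savi])


def week_of_doy(doy) -> np.ndarray:
    """Week slot floor((doy-1)/7), with days 365/366 folded into week 51."""
    return np.minimum((np.asarray(doy, int) - 1) // 7, N_WEEKS - 1)


def encode_weekly(series: ObservationSeries) -> EncodedSample:
    """Average clear observations per calendar week; empty weeks are 0."""
    s = series.clear_only()
    matrix = np.zeros((N_WEEKS, N_BANDS))
    if s.n_obs:
        vals = with_indices(s.values)
        weeks = week_of_doy(s.doy)
        counts = np.bincount(weeks, minlength=N_WEEKS).astype(float)
        for b in range(N_BANDS):
            sums = np.bincount(weeks, weights=vals[:, b], minlength=N_WEEKS)
            nz = counts > 0
            matrix[nz, b] = sums[nz] / counts[nz]
    return EncodedSample(matrix=matrix, year=series.year, label=None)


def encode_many(series_list, labels=None) -> tuple[np.ndarray, np.ndarray | None]:
    """Stack encodings into (n, 52, 9); optionally with a label vector."""
    X = np.stack([encode_weekly(s).matrix for s in series_list]) if series_list else \
        np.zeros((0, N_WEEKS, N_BANDS))
    y = None if labels is None else np.asarray(labels, int)
    return X, y


def save_encoded(path, X: np.ndarray, manifest: "object") -> None:
    """Persist encoded samples as NPZ plus a CSV manifest alongside.

    `manifest` is a DataFrame-like with one row per sample (id, year,
    label, tile ...); it is written next to the NPZ with suffix .csv.
    """
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(path, X=np.asarray(X))
    manifest.to_csv(path.with_suffix(".csv"), index=False)


def load_encoded(path):
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    X = np.load(path.with_suffix(".npz"))["X"]
    manifest = pd.read_csv(path.with_suffix(".csv"))
    return X, manifest


def compute_cso(series_by_year: dict[int, ObservationSeries]) -> dict[int, int]:
    """Annual clear-sky observation counts for one pixel."""
    return {year: int(np.asarray(s.clear, bool).sum()) for year, s in series_by_year.items()}


# ---------------------------------------------------------------------------
# augmentations

def augment_random_obs_selection(
    series: ObservationSeries,
    keep_fraction_range: tuple[float, float],
    rng: np.random.Generator,
) -> ObservationSeries:
    """Thin the series: draw a keep fraction, keep each observation i.i.d.

    At least one observation is retained when the input is non-empty;
    kept observations are unmodified.
    """
    lo, hi = keep_fraction_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("keep fractions must satisfy 0 < lo <= hi <= 1")
    if series.n_obs == 0:
        return series
    p = rng.uniform(lo, hi)
    keep = rng.random(series.n_obs) < p
    if not keep.any():
        keep[rng.integers(series.n_obs)] = True
    return replace(
        series,
        doy=np.asarray(series.doy)[keep],
        values=np.asarray(series.values)[keep],
        clear=np.asarray(series.clear)[keep],
    )


def augment_random_day_shift(
    series: ObservationSeries, max_shift_days: int, rng: np.random.Generator
) -> ObservationSeries:
    """Shift every DOY by one common offset in [-max, +max]; drop dates leaving [1, 365]."""
    if max_shift_days < 0:
        raise ValueError("max_shift_days must be >= 0")
    if max_shift_days == 0 or series.n_obs == 0:
        return series
    offset = int(rng.integers(-max_shift_days, max_shift_days + 1))
    doy = np.asarray(series.doy) + offset
    keep = (doy >= 1) & (doy <= 365)
    return replace(
        series,
        doy=doy[keep],
        values=np.asarray(series.values)[keep],
        clear=np.asarray(series.clear)[keep],
    )
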