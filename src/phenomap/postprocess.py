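"""Post-classification noise filters for annual label maps.

Three filters clean the raw per-pixel predictions:

* spatial majority filter (both levels): an isolated pixel — one whose
  class differs from all eight neighbours — takes the modal class of its
  3x3 window; evaluated on a frozen copy of the input, border pixels
  unchanged, ties broken toward the smallest class code;
* temporal filter (Level 1): a 3-year window slides backwards through
  the years; a one-year blip (X, Y, X) becomes (X, X, X), with updates
  visible to subsequent (earlier) windows;
* spatio-temporal filter (Level 2): a 3x3x3 cube slides backwards; when
  the same class fills all nine pixels of a patch in the years before
  and after, and at least seven of the nine centre-year pixels already
  agree, the centre patch is converted. Alternating crop sequences are
  deliberately left alone, which is why the plain temporal filter is not
  applied to crop maps.

Any window containing nodata is skipped.
"""

from __future__ import annotations

import numpy as np

from .cube import LabelCube
from .legend import NODATA


def spatial_majority_filter(grid: np.ndarray, nodata: int = NODATA) -> np.ndarray:
    """3x3 majority filter firing only on pixels isolated from all 8 neighbours."""
    grid = np.asarray(grid)
    out = grid.copy()
    rows, cols = grid.shape
    for r in range(1, rows - 1):
        for c in range(1, cols - 1):
            center = grid[r, c]
            window = grid[r - 1:r + 2, c - 1:c + 2]
            if nodata in window:
                continue
            neigh = np.delete(window.ravel(), 4)
            if np.any(neigh == center):
                continue
            codes, counts = np.unique(neigh, return_counts=True)
            out[r, c] = codes[counts.argmax()]  # np.unique sorts: ties -> smallest
    return out


def temporal_filter(cube: LabelCube) -> LabelCube:
    """Backward 3-year window replacing one-year blips (X, Y, X) -> (X, X, X)."""
    if len(cube.years) < 3:
        raise ValueError("temporal filter needs at least 3 years")
    out = cube.copy()
    d = out.data
    for t in range(len(cube.years) - 2, 0, -1):  # latest centre first
        before, centre, after = d[t - 1], d[t], d[t + 1]
        fix = (
            (before == after) & (centre != before)
            & (before != cube.nodata) & (centre != cube.nodata) & (after != cube.nodata)
        )
        centre[fix] = before[fix]
    return out


def spatiotemporal_filter(cube: LabelCube) -> LabelCube:
    """Backward 3x3x3 cube filter converting near-homogeneous one-year patches.

    For centre year t (processed from latest to earliest, updates in
    place across years) and each 3x3 patch: if years t-1 and t+1 are
    filled by the same class c over the whole patch, and >= 7 of the 9
    centre-year pixels equal c, the centre-year patch becomes c. Within
    one year, conditions are evaluated on a frozen copy of that year.
    """
    if len(cube.years) < 3:
        raise ValueError("spatio-temporal filter needs at least 3 years")
    rows, cols = cube.shape
    if rows < 3 or cols < 3:
        raise ValueError("spatio-temporal filter needs a grid of at least 3x3")
    out = cube.copy()
    d = out.data
    for t in range(len(cube.years) - 2, 0, -1):
        frozen = d[t].copy()
        for r in range(1, rows - 1):
            for c in range(1, cols - 1):
                sl = (slice(r - 1, r + 2), slice(c - 1, c + 2))
                before = d[t - 1][sl]
                after = d[t + 1][sl]
                centre = frozen[sl]
                if (before == cube.nodata).any() or (after == cube.nodata).any() \
                        or (centre == cube.nodata).any():
                    continue
                cls = before[0, 0]
                if not ((before == cls).all() and (after == cls).all()):
                    continue
                if (centre == cls).sum() >= 7:
                    d[t][sl] = cls
    return out


def level1_bundle(cube: LabelCube) -> LabelCube:
    """Level-1 cleanup: per-year spatial majority, then the temporal filter."""
    out = cube.copy()
    for i in range(len(out.years)):
        out.data[i] = spatial_majority_filter(out.data[i], out.nodata)
    return temporal_filter(out)


def level2_bundle(cube: LabelCube) -> LabelCube:
    """Level-2 cleanup: per-year spatial majority, then the spatio-temporal filter."""
    out = cube.copy()
    for i in range(len(out.years)):
        out.data[i] = spatial_majority_filter(out.data[i], out.nodata)
    return spatiotemporal_filter(out)
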