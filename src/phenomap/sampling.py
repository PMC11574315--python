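"""Rule-based mining of training pixels from reference-product stacks.

Ten semi-automated rules select pixels whose land cover is consistent
(invariant) across the reference years, by intersecting thresholds on
imperviousness, tree-cover density, forest type, CLC-like and N2K-like
categorical codes, and spectral-temporal metrics (index percentiles over
the multi-year period). A condition is evaluated per pixel per required
year and combined with AND; focal conditions additionally require every
pixel of a 5x5 window (or the 24 surrounding ring pixels) to satisfy the
predicate. Windows touching nodata or the raster edge are ineligible.

Crop training labels come from parcel geometries instead, rasterized by
pixel-center-in-polygon with overlapping parcels discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geoio import GeoTransform
from .legend import CROP_GRASS_CODES, L1_CROP_GRASS
from .synthetic import (
    CLC_CODES,
    FOREST_TYPE_CODES,
    N2K_CODES,
    IMPERVIOUSNESS_YEARS,
    TREE_DENSITY_YEARS,
    ReferenceStack,
)

CATEGORICAL_YEARS = (2006, 2012, 2018)
STM_PERIOD = (2006, 2018)

_OPS = {
    ">": np.greater,
    "<": np.less,
    ">=": np.greater_equal,
    "<=": np.less_equal,
    "==": np.equal,
}


@dataclass(frozen=True)
class Condition:
    """One predicate of a sampling rule.

    kind "cmp": product `op` threshold; kind "in_set": product code in
    `codes`; kind "paired_class": the CLC-like and N2K-like products map
    to the same subclass, drawn from `pairs` of (clc_code, n2k_code).
    """

    kind: str  # "cmp" | "in_set" | "paired_class"
    product: str | tuple[str, str]
    years: tuple[int | None, ...]
    op: str = "=="
    threshold: float = 0.0
    codes: tuple[int, ...] = ()
    pairs: tuple[tuple[int, int], ...] = ()
    window: int = 1  # 1 (center pixel) or 5 (focal)
    quantifier: str = "center"  # "center" | "window" | "ring"


@dataclass(frozen=True)
class RuleSpec:
    name: str
    target_code: int  # final legend code 1..9, or Level-1 code for Crop&Grass
    target_level: int
    conditions: tuple[Condition, ...]


def compute_stm(
    series_map: dict[tuple[int, int], dict[int, "object"]],
    shape: tuple[int, int],
    index: str,
    percentile: float,
) -> np.ndarray:
    """Per-pixel percentile of an index over all clear observations of the period.

    Uses the linear-interpolation percentile definition. Pixels with no
    clear observation get NaN (nodata) and are excluded from all rules.
    """
    from .encoding import with_indices

    col = {"ndvi": 6, "ndwi": 7, "savi": 8}[index]
    out = np.full(shape, np.nan)
    for (r, c), per_year in series_map.items():
        vals = []
        for s in per_year.values():
            s = s.clear_only()
            if s.n_obs:
                vals.append(with_indices(s.values)[:, col])
        if vals:
            out[r, c] = np.percentile(np.concatenate(vals), percentile)
    return out


def add_stm_products(stack: ReferenceStack, series_map, shape) -> ReferenceStack:
    """Attach the four index-percentile rasters the rules need."""
    for name, index, pct in (
        ("ndvi_p10", "ndvi", 10), ("ndvi_p90", "ndvi", 90),
        ("ndwi_p10", "ndwi", 10), ("ndwi_p90", "ndwi", 90),
    ):
        stack.add(name, None, compute_stm(series_map, shape, index, pct))
    return stack


def _predicate(stack: ReferenceStack, cond: Condition) -> np.ndarray:
    """Per-pixel boolean: condition holds in ALL its required years; NaN fails."""
    result = None
    for year in cond.years:
        if cond.kind == "paired_class":
            p1, p2 = cond.product
            a = stack.get(p1, year)
            b = stack.get(p2, year)
            ok = np.zeros(a.shape, bool)
            for ca, cb in cond.pairs:
                ok |= (a == ca) & (b == cb)
        else:
            raster = stack.get(cond.product, year)
            valid = ~np.isnan(np.asarray(raster, float))
            if cond.kind == "cmp":
                with np.errstate(invalid="ignore"):
                    ok = _OPS[cond.op](raster, cond.threshold) & valid
            elif cond.kind == "in_set":
                ok = np.isin(raster, cond.codes) & valid
            else:
                raise ValueError(f"unknown condition kind {cond.kind!r}")
        result = ok if result is None else (result & ok)
    return result


def _apply_quantifier(pred: np.ndarray, cond: Condition) -> np.ndarray:
    if cond.window == 1 or cond.quantifier == "center":
        return pred
    if cond.window != 5:
        raise ValueError("focal window size must be 1 or 5")
    if cond.quantifier == "window":
        footprint = np.ones((5, 5), bool)
    elif cond.quantifier == "ring":
        footprint = np.ones((5, 5), bool)
        footprint[2, 2] = False
    else:
        raise ValueError(f"unknown quantifier {cond.quantifier!r}")
    # minimum filter = ALL-quantifier; constant False padding makes edge
    # windows (which stick out of the raster) ineligible
    return ndimage.minimum_filter(
        pred.astype(np.uint8), footprint=footprint, mode="constant", cval=0
    ).astype(bool)


def evaluate_rule(stack: ReferenceStack, rule: RuleSpec) -> np.ndarray:
    """Boolean eligibility mask: a pixel qualifies iff ALL conditions hold."""
    mask = None
    for cond in rule.conditions:
        layer = _apply_quantifier(_predicate(stack, cond), cond)
        mask = layer if mask is None else (mask & layer)
    return mask


# ---------------------------------------------------------------------------
# the ten built-in rules


def builtin_rules() -> list[RuleSpec]:
    """The ten invariant-class sampling rules, thresholds transcribed verbatim."""
    C = Condition
    imperv0 = C("cmp", "imperviousness", IMPERVIOUSNESS_YEARS, "==", 0.0)
    shrub_pairs = tuple(
        (CLC_CODES[k], N2K_CODES[k])
        for k in ("moors_heathland", "sclerophyllous", "transitional_woodland")
    )
    cropgrass_pairs = tuple(
        (CLC_CODES[k], N2K_CODES[k])
        for k in ("arable", "pasture", "natural_grassland")
    )
    marsh_clc = (CLC_CODES["inland_marsh"], CLC_CODES["salt_marsh"])
    marsh_n2k = (N2K_CODES["inland_marsh"], N2K_CODES["salt_marsh"])
    w5 = dict(window=5, quantifier="window")
    return [
        RuleSpec("Built-up", 1, 2, (
            C("cmp", "imperviousness", IMPERVIOUSNESS_YEARS, ">", 20.0,
              window=5, quantifier="ring"),
            C("cmp", "imperviousness", IMPERVIOUSNESS_YEARS, ">", 50.0),
        )),
        RuleSpec("Bareland", 2, 2, (
            C("cmp", "ndvi_p90", (None,), "<", 0.3),
            C("cmp", "ndwi_p90", (None,), "<", 0.0),
            imperv0,
        )),
        RuleSpec("Water", 3, 2, (
            C("cmp", "ndwi_p10", (None,), ">", 0.3),
            C("cmp", "ndvi_p90", (None,), "<", 0.3),
            imperv0,
        )),
        RuleSpec("Shrubland", 4, 2, (
            C("paired_class", ("clc_code", "n2k_code"), CATEGORICAL_YEARS,
              pairs=shrub_pairs),
            C("cmp", "tree_density", TREE_DENSITY_YEARS, "<", 30.0),
            imperv0,
        )),
        RuleSpec("Coniferous forest", 5, 2, (
            C("in_set", "clc_code", CATEGORICAL_YEARS,
              codes=(CLC_CODES["coniferous"],), **w5),
            C("in_set", "forest_type", (2012, 2015, 2018),
              codes=(FOREST_TYPE_CODES["coniferous"],), **w5),
            C("cmp", "tree_density", TREE_DENSITY_YEARS, ">", 75.0, **w5),
        )),
        RuleSpec("Broadleaf forest", 6, 2, (
            C("in_set", "clc_code", CATEGORICAL_YEARS,
              codes=(CLC_CODES["broadleaf"],), **w5),
            C("in_set", "forest_type", (2006, 2012, 2018),
              codes=(FOREST_TYPE_CODES["broadleaf"],), **w5),
            C("cmp", "tree_density", TREE_DENSITY_YEARS, ">", 75.0, **w5),
        )),
        RuleSpec("Wetland marsh", 7, 2, (
            C("in_set", "clc_code", CATEGORICAL_YEARS, codes=marsh_clc, **w5),
            C("in_set", "n2k_code", CATEGORICAL_YEARS, codes=marsh_n2k, **w5),
        )),
        RuleSpec("Exploited peat bog", 8, 2, (
            C("in_set", "clc_code", CATEGORICAL_YEARS,
              codes=(CLC_CODES["peat_bog"],), **w5),
            C("in_set", "n2k_code", CATEGORICAL_YEARS,
              codes=(N2K_CODES["exploited_peat"],), **w5),
        )),
        RuleSpec("Unexploited peat bog", 9, 2, (
            C("in_set", "clc_code", CATEGORICAL_YEARS,
              codes=(CLC_CODES["peat_bog"],), **w5),
            C("in_set", "n2k_code", CATEGORICAL_YEARS,
              codes=(N2K_CODES["unexploited_peat"],), **w5),
        )),
        RuleSpec("Cropland and grassland", L1_CROP_GRASS, 1, (
            C("paired_class", ("clc_code", "n2k_code"), CATEGORICAL_YEARS,
              pairs=cropgrass_pairs),
            C("cmp", "tree_density", TREE_DENSITY_YEARS, "==", 0.0, **w5),
            C("cmp", "imperviousness", IMPERVIOUSNESS_YEARS, "==", 0.0, **w5),
        )),
    ]


INVARIANT_CLASS_CAP = 10_000  # training pixels per invariant class
CROP_CLASS_CAP = 50_000  # training pixels per crop class per labeled year


def sample_points(
    mask: np.ndarray, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw min(cap, eligible) pixel indices uniformly without replacement."""
    if cap <= 0:
        raise ValueError("cap must be > 0")
    eligible = np.argwhere(mask)
    if len(eligible) == 0:
        warnings.warn("no eligible pixels for rule; returning empty sample",
                      stacklevel=2)
        return np.zeros((0, 2), int)
    take = min(cap, len(eligible))
    return eligible[rng.choice(len(eligible), size=take, replace=False)]


# ---------------------------------------------------------------------------
# crop parcels


@dataclass(frozen=True)
class CropParcel:
    geometry: object  # shapely polygon in the pipeline CRS
    year: int
    class_code: int


def rasterize_crop_parcels(
    parcels: list[CropParcel],
    transform: GeoTransform,
    shape: tuple[int, int],
) -> dict[int, np.ndarray]:
    """Pixel-center-in-polygon labeling per year; overlap pixels become 0."""
    from shapely import contains_xy

    for p in parcels:
        if p.class_code not in CROP_GRASS_CODES:
            raise ValueError(f"unknown crop label {p.class_code}")
    rows, cols = shape
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    xs = transform.x0 + (jj + 0.5) * transform.pixel_size
    ys = transform.y0 - (ii + 0.5) * transform.pixel_size
    out: dict[int, np.ndarray] = {}
    cover: dict[int, np.ndarray] = {}
    for p in parcels:
        lab = out.setdefault(p.year, np.zeros(shape, int))
        cov = cover.setdefault(p.year, np.zeros(shape, int))
        inside = contains_xy(p.geometry, xs.ravel(), ys.ravel()).reshape(shape)
        lab[inside] = p.class_code
        cov[inside] += 1
    for year, cov in cover.items():
        out[year][cov > 1] = 0
    return out
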