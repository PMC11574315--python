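"""Synthetic scenes with the statistical structure of annual land-cover mapping.

The generator emulates, offline, the features of real satellite archives
that the pipeline is built around:

* class-specific annual phenologies — each class has a double-logistic
  seasonal greenness curve mixed between a per-band dormant ("base")
  spectrum and a peak-season spectrum, with additive Gaussian noise;
* irregular, year-dependent acquisition: clear-sky dates are drawn from
  a Poisson process with a seasonal weighting, sparse in the early
  Landsat-only era (~8 clear obs/yr) and dense after 2015 (~30/yr);
* patchy landscapes where non-crop classes persist across years, crop
  fields rotate between crop types with a configurable transition
  matrix, and unexploited peat bogs are progressively converted to
  exploited extraction surfaces;
* reference-product stacks (imperviousness %, tree-cover density %,
  forest type, CLC-like and N2K-like categorical codes) derived from the
  truth with configurable contamination/disagreement, so the rule-based
  training-data miner can be exercised and checked.

All randomness flows through a single `numpy` Generator so any output is
bit-reproducible given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cube import LabelCube
from .encoding import ObservationSeries, week_of_doy
from .geoio import GeoTransform
from .legend import CROP_CODES, DEFAULT_LEGEND

BANDS = ("red", "green", "blue", "nir", "swir1", "swir2")

SENTINEL2_ERA = 2015  # first dense-acquisition year


# ---------------------------------------------------------------------------
# phenology


@dataclass(frozen=True)
class PhenologyModel:
    """Double-logistic seasonal model for one class.

    Per band b: refl_b(t) = base_b + amplitude_b * s(t), where
    s(t) = 1/(1+exp(-rate_up*(t-greenup))) + 1/(1+exp(rate_down*(t-senescence))) - 1
    rises from ~0 in winter to ~1 at mid-season. Gaussian noise with
    `noise_sd` is added per observation and the result clipped to [0, 1].
    """

    class_code: int
    base: tuple[float, ...]  # 6 reflectance fractions at dormancy
    amplitude: tuple[float, ...]  # per-band seasonal change (may be negative)
    greenup: float  # DOY of green-up inflection
    senescence: float  # DOY of senescence inflection
    rate_up: float = 0.10  # 1/day
    rate_down: float = 0.08
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        for b, a in zip(self.base, self.amplitude):
            if not (0 <= b <= 1 and 0 <= b + a <= 1):
                raise ValueError("base and base+amplitude must lie in [0, 1]")
        if self.greenup >= self.senescence:
            raise ValueError("green-up day must precede senescence day")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def seasonal(self, doy) -> np.ndarray:
        t = np.asarray(doy, float)
        up = 1.0 / (1.0 + np.exp(-self.rate_up * (t - self.greenup)))
        down = 1.0 / (1.0 + np.exp(self.rate_down * (t - self.senescence)))
        return up + down - 1.0

    def curve(self, doy) -> np.ndarray:
        """Noise-free reflectances, shape (n_dates, 6)."""
        s = self.seasonal(doy)[:, None]
        return np.clip(np.asarray(self.base) + np.asarray(self.amplitude) * s, 0.0, 1.0)


def simulate_phenology(
    model: PhenologyModel,
    dates,
    rng: np.random.Generator,
    year: int = 2018,
) -> ObservationSeries:
    """Sample the class curve at `dates` (DOY) with additive Gaussian noise."""
    doy = np.asarray(dates, int)
    if doy.size and (doy.min() < 1 or doy.max() > 365):
        raise ValueError("dates must lie within [1, 365]")
    values = model.curve(doy)
    if model.noise_sd > 0 and doy.size:
        values = np.clip(values + rng.normal(0, model.noise_sd, values.shape), 0.0, 1.0)
    return ObservationSeries(
        year=year, doy=doy, values=values, clear=np.ones(doy.size, bool)
    )


def _flat(base, noise=0.02):
    return {"base": base, "amplitude": (0.0,) * 6, "greenup": 100.0,
            "senescence": 280.0, "noise_sd": noise}


def _veg(base, peak, greenup, senescence, rate_up=0.10, rate_down=0.08, noise=0.02):
    amp = tuple(p - b for b, p in zip(base, peak))
    return {"base": base, "amplitude": amp, "greenup": greenup,
            "senescence": senescence, "rate_up": rate_up, "rate_down": rate_down,
            "noise_sd": noise}


# Band order: red, green, blue, nir, swir1, swir2.
_SOIL = (0.17, 0.15, 0.11, 0.24, 0.30, 0.26)  # bright arable soil
_GREEN = (0.04, 0.08, 0.03, 0.50, 0.22, 0.12)  # dense green canopy

_DEFAULT_PARAMS: dict[int, dict] = {
    1: _flat((0.19, 0.18, 0.16, 0.23, 0.25, 0.23)),  # Built-up: stable, bright
    2: _flat((0.24, 0.21, 0.17, 0.30, 0.36, 0.32)),  # Bareland: stable, brighter
    3: _flat((0.03, 0.06, 0.06, 0.01, 0.005, 0.005), noise=0.005),  # Water: dark NIR/SWIR
    4: _veg((0.11, 0.10, 0.07, 0.22, 0.25, 0.19),  # Shrubland: muted season
            (0.06, 0.09, 0.04, 0.37, 0.22, 0.14), 105, 295),
    5: _veg((0.035, 0.055, 0.03, 0.28, 0.13, 0.07),  # Coniferous: evergreen
            (0.03, 0.06, 0.025, 0.34, 0.12, 0.06), 110, 290),
    6: _veg((0.08, 0.08, 0.06, 0.20, 0.19, 0.13),  # Broadleaf: strong season
            (0.04, 0.09, 0.03, 0.52, 0.20, 0.10), 118, 288),
    7: _veg((0.05, 0.08, 0.06, 0.13, 0.08, 0.05),  # Marsh: wet background
            (0.04, 0.09, 0.04, 0.42, 0.14, 0.07), 128, 284),
    8: _flat((0.10, 0.09, 0.07, 0.12, 0.17, 0.15)),  # Exploited bog: dark bare peat
    9: _veg((0.07, 0.08, 0.05, 0.21, 0.13, 0.08),  # Unexploited bog: moss, long season
            (0.05, 0.08, 0.04, 0.36, 0.13, 0.07), 92, 306),
    # Crops share the soil background; they differ in sowing/harvest timing
    # (winter vs spring cereals etc.) and peak canopy.
    10: _veg(_SOIL, (0.04, 0.08, 0.03, 0.50, 0.22, 0.12), 74, 196, 0.12, 0.12),  # Wheat (winter)
    11: _veg(_SOIL, (0.05, 0.08, 0.03, 0.47, 0.23, 0.13), 110, 204, 0.12, 0.13),  # Barley (spring)
    12: _veg(_SOIL, (0.05, 0.08, 0.03, 0.44, 0.24, 0.14), 58, 184, 0.11, 0.12),  # Rye (early winter)
    13: _veg(_SOIL, (0.05, 0.08, 0.03, 0.48, 0.22, 0.13), 128, 228, 0.12, 0.12),  # Oats (late spring)
    14: _veg(_SOIL, (0.04, 0.08, 0.03, 0.55, 0.21, 0.11), 162, 282, 0.11, 0.10),  # Maize
    15: _veg(_SOIL, (0.05, 0.12, 0.04, 0.52, 0.20, 0.11), 70, 202, 0.10, 0.11),  # Seed crops (rape)
    16: _veg(_SOIL, (0.05, 0.09, 0.03, 0.50, 0.23, 0.12), 150, 296, 0.10, 0.09),  # Root crops
    17: _veg(_SOIL, (0.05, 0.09, 0.03, 0.45, 0.22, 0.13), 136, 246, 0.11, 0.11),  # Pulses, vegetables
    18: _veg((0.09, 0.10, 0.06, 0.30, 0.24, 0.17),  # Grassland: green most of the year
             (0.05, 0.09, 0.04, 0.45, 0.20, 0.12), 84, 314, 0.09, 0.08),
}


def default_phenologies(noise_sd: float | None = None) -> dict[int, PhenologyModel]:
    """Package-default phenology table for all 18 classes."""
    out = {}
    for code, params in _DEFAULT_PARAMS.items():
        if noise_sd is not None:
            params = {**params, "noise_sd": noise_sd}
        out[code] = PhenologyModel(class_code=code, **params)
    return out


# ---------------------------------------------------------------------------
# acquisitions


@dataclass(frozen=True)
class AcquisitionProfile:
    """Expected clear-sky observation count and its seasonal distribution."""

    year: int
    expected_clear_obs: float
    week_weights: tuple[float, ...] = ()  # 52 nonnegative weights; empty = default

    def __post_init__(self) -> None:
        if self.expected_clear_obs <= 0:
            raise ValueError("expected_clear_obs must be > 0")
        if self.week_weights and (len(self.week_weights) != 52
                                  or min(self.week_weights) < 0):
            raise ValueError("week_weights must be 52 nonnegative values")

    def weights(self) -> np.ndarray:
        if self.week_weights:
            w = np.asarray(self.week_weights, float)
        else:
            # mild summer bias: clearer skies in the growing season
            w = 0.6 + np.sin(np.pi * np.arange(52) / 51.0) ** 2
        return w / w.sum()


def default_profile(year: int) -> AcquisitionProfile:
    """Sparse Landsat-only era (~8 clear obs/yr) before 2015, dense (~30/yr) after."""
    rate = 30.0 if year >= SENTINEL2_ERA else 8.0
    return AcquisitionProfile(year=year, expected_clear_obs=rate)


def simulate_acquisitions(
    profile: AcquisitionProfile, rng: np.random.Generator
) -> np.ndarray:
    """Clear-sky DOYs: Poisson count thinned over the seasonal weighting."""
    n = int(rng.poisson(profile.expected_clear_obs))
    if n == 0:
        return np.zeros(0, int)
    day_p = profile.weights()[week_of_doy(np.arange(1, 366))]
    day_p = day_p / day_p.sum()
    days = rng.choice(np.arange(1, 366), size=min(n, 365), replace=False, p=day_p)
    return np.sort(days)


# ---------------------------------------------------------------------------
# landscape


@dataclass
class SceneConfig:
    """Study conditions for one synthetic scene."""

    shape: tuple[int, int] = (40, 40)
    years: list[int] = field(default_factory=lambda: list(range(2016, 2022)))
    classes: tuple[int, ...] = tuple(range(1, 19))
    n_patches: int = 25
    rotation: dict[int, dict[int, float]] | None = None  # crop code -> {code: prob}
    peat_expansion_rate: int = 4  # unexploited-bog pixels converted per year
    season_jitter_sd: float = 3.0  # per pixel-year DOY shift of the season (days)
    noise_sd: float | None = None  # override phenology noise if set
    profiles: dict[int, AcquisitionProfile] | None = None
    seed: int = 0
    observation_seed: int | None = None  # decouple weather/noise from layout

    def acquisition(self, year: int) -> AcquisitionProfile:
        if self.profiles and year in self.profiles:
            return self.profiles[year]
        return default_profile(year)


def default_rotation(stay: float = 0.55) -> dict[int, dict[int, float]]:
    """Crop rotation: stay with probability `stay`, else uniform over other crops."""
    rot = {}
    others = {c: (1 - stay) / (len(CROP_CODES) - 1) for c in CROP_CODES}
    for c in CROP_CODES:
        row = dict(others)
        row[c] = stay
        rot[c] = row
    return rot


def _check_rotation(rot: dict[int, dict[int, float]]) -> None:
    for c, row in rot.items():
        if abs(sum(row.values()) - 1.0) > 1e-9:
            raise ValueError(f"rotation row for class {c} does not sum to 1")


@dataclass
class Scene:
    """A simulated world: truth cube, per-pixel series, and patch bookkeeping."""

    truth: LabelCube
    series: dict[tuple[int, int], dict[int, ObservationSeries]]
    patch_id: np.ndarray  # (rows, cols) int patch membership
    config: SceneConfig

    def series_for(self, row: int, col: int, year: int) -> ObservationSeries:
        return self.series[(row, col)][year]


def _patch_map(shape, n_patches, classes, rng) -> tuple[np.ndarray, np.ndarray]:
    """Voronoi patches around random seeds; classes allocated round-robin."""
    rows, cols = shape
    # jittered-grid seeds give compact, field-like patches of similar size
    k = int(np.ceil(np.sqrt(n_patches)))
    centers = [
        (rows * (i + 0.5) / k, cols * (j + 0.5) / k) for i in range(k) for j in range(k)
    ]
    centers = [centers[i] for i in rng.permutation(len(centers))[:n_patches]]
    jitter = rng.uniform(-0.25, 0.25, (n_patches, 2)) * np.array([rows / k, cols / k])
    seeds = np.asarray(centers) + jitter
    # round-robin so every class owns roughly n_patches/len(classes) patches
    patch_class = np.array(
        [classes[i % len(classes)] for i in range(n_patches)], int
    )
    rng.shuffle(patch_class)
    rr, cc = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
    _, idx = cKDTree(seeds).query(pts)
    return idx.reshape(shape), patch_class


def simulate_landscape(config: SceneConfig) -> Scene:
    """Generate the truth cube and all per-pixel, per-year observation series."""
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    rotation = config.rotation if config.rotation is not None else default_rotation()
    _check_rotation(rotation)

    patch_id, patch_class = _patch_map(config.shape, config.n_patches,
                                       config.classes, rng)
    years = list(config.years)
    n_years = len(years)

    # per-patch class trajectory: crops rotate, everything else persists
    patch_traj = np.zeros((n_years, config.n_patches), int)
    patch_traj[0] = patch_class
    crop_set = set(rotation)
    for t in range(1, n_years):
        prev = patch_traj[t - 1]
        nxt = prev.copy()
        for p in range(config.n_patches):
            c = int(prev[p])
            if c in crop_set:
                row = rotation[c]
                codes = np.array(sorted(row), int)
                probs = np.array([row[k] for k in codes])
                nxt[p] = codes[rng.choice(len(codes), p=probs)]
        patch_traj[t] = nxt

    data = patch_traj[:, patch_id]  # (n_years, rows, cols)

    # peat-bog exploitation: convert unexploited (9) pixels to exploited (8),
    # preferring pixels that touch already-exploited ones
    data = data.copy()
    for t in range(1, n_years):
        data[t][data[t - 1] == 8] = 8  # conversion is permanent
        quota = config.peat_expansion_rate
        if quota <= 0:
            continue
        unexp = np.argwhere(data[t] == 9)
        if len(unexp) < quota:
            warnings.warn(
                f"peat expansion capped at {len(unexp)} pixels in year {years[t]}",
                stacklevel=2,
            )
            quota = len(unexp)
        if quota == 0:
            continue
        exploited = data[t] == 8
        if exploited.any():
            from scipy.ndimage import binary_dilation

            frontier = binary_dilation(exploited) & (data[t] == 9)
            cand = np.argwhere(frontier)
        else:
            cand = unexp
        if len(cand) < quota:
            extra = np.array([p for p in unexp.tolist() if p not in cand.tolist()])
            cand = np.vstack([cand, extra]) if len(extra) else cand
        pick = cand[rng.choice(len(cand), size=min(quota, len(cand)), replace=False)]
        data[t][pick[:, 0], pick[:, 1]] = 8

    transform = GeoTransform(4_500_000.0, 3_300_000.0, 30.0)
    truth = LabelCube(years, data, transform)

    phen = default_phenologies(config.noise_sd)
    if config.observation_seed is not None:
        rng = np.random.default_rng(config.observation_seed)
    series: dict[tuple[int, int], dict[int, ObservationSeries]] = {}
    for r in range(rows):
        for c in range(cols):
            per_year = {}
            for t, year in enumerate(years):
                dates = simulate_acquisitions(config.acquisition(year), rng)
                model = phen[int(data[t, r, c])]
                if config.season_jitter_sd > 0:
                    shift = rng.normal(0, config.season_jitter_sd)
                    model = PhenologyModel(
                        class_code=model.class_code, base=model.base,
                        amplitude=model.amplitude,
                        greenup=model.greenup + shift,
                        senescence=model.senescence + shift,
                        rate_up=model.rate_up, rate_down=model.rate_down,
                        noise_sd=model.noise_sd,
                    )
                per_year[year] = simulate_phenology(model, dates, rng, year=year)
            series[(r, c)] = per_year
    return Scene(truth=truth, series=series, patch_id=patch_id, config=config)


# ---------------------------------------------------------------------------
# reference products

# Synthetic stand-ins for the categorical reference products. The code
# dictionaries are package constants; they mirror product semantics (CLC
# does not separate exploited from unexploited peat bog, the N2K-like
# product does), not the real products' code lists.
CLC_CODES = {
    "builtup": 111, "arable": 211, "pasture": 231, "natural_grassland": 321,
    "moors_heathland": 322, "sclerophyllous": 323, "transitional_woodland": 324,
    "broadleaf": 311, "coniferous": 312, "bareland": 331, "inland_marsh": 411,
    "peat_bog": 412, "salt_marsh": 421, "water": 512,
}
N2K_CODES = {
    "builtup": 505, "bareland": 610, "arable": 710, "pasture": 720,
    "natural_grassland": 730, "moors_heathland": 802, "sclerophyllous": 803,
    "transitional_woodland": 804, "broadleaf": 810, "coniferous": 820,
    "inland_marsh": 910, "salt_marsh": 920, "exploited_peat": 931,
    "unexploited_peat": 932, "water": 940,
}
FOREST_TYPE_CODES = {"nonforest": 0, "broadleaf": 1, "coniferous": 2}

IMPERVIOUSNESS_YEARS = (2006, 2009, 2012, 2015, 2018)
TREE_DENSITY_YEARS = (2012, 2015, 2018)
FOREST_TYPE_YEARS = (2006, 2012, 2015, 2018)
CATEGORICAL_YEARS = (2006, 2012, 2018)

# truth class -> (clc key, n2k key, forest type key)
_CLASS_TO_PRODUCT = {
    1: ("builtup", "builtup", "nonforest"),
    2: ("bareland", "bareland", "nonforest"),
    3: ("water", "water", "nonforest"),
    4: ("moors_heathland", "moors_heathland", "nonforest"),
    5: ("coniferous", "coniferous", "coniferous"),
    6: ("broadleaf", "broadleaf", "broadleaf"),
    7: ("inland_marsh", "inland_marsh", "nonforest"),
    8: ("peat_bog", "exploited_peat", "nonforest"),
    9: ("peat_bog", "unexploited_peat", "nonforest"),
    18: ("pasture", "pasture", "nonforest"),
}
for _c in CROP_CODES:
    _CLASS_TO_PRODUCT[_c] = ("arable", "arable", "nonforest")


@dataclass
class ReferenceStack:
    """Per-year product rasters plus period spectral-temporal metric rasters.

    `products[name][year]` is a 2-D array; period metrics (e.g.
    "ndvi_p90") are keyed with year None.
    """

    products: dict[str, dict[int | None, np.ndarray]]

    def get(self, name: str, year: int | None = None) -> np.ndarray:
        if name not in self.products or year not in self.products[name]:
            raise KeyError(f"reference product {name!r} for year {year!r} is missing")
        return self.products[name][year]

    def add(self, name: str, year: int | None, raster: np.ndarray) -> None:
        self.products.setdefault(name, {})[year] = raster


def simulate_reference_products(
    truth: LabelCube,
    rng: np.random.Generator,
    contamination: float = 0.0,
    disagreement: float = 0.0,
) -> ReferenceStack:
    """Derive product stacks from the truth map (first-year grid for invariants).

    `contamination` perturbs the continuous layers (a pixel's value is
    replaced by a uniform draw on [0, 100] with this probability);
    `disagreement` relabels categorical pixels to a random other code.
    """
    base = truth.data[0]
    rows, cols = base.shape
    stack = ReferenceStack(products={})

    def contaminate(raster):
        if contamination > 0:
            m = rng.random(raster.shape) < contamination
            raster = np.where(m, rng.uniform(0, 100, raster.shape), raster)
        return raster

    def disagree(raster, alphabet):
        if disagreement > 0:
            m = rng.random(raster.shape) < disagreement
            repl = np.asarray(alphabet)[rng.integers(0, len(alphabet), raster.shape)]
            # force a change where the random replacement equals the original
            clash = m & (repl == raster)
            while clash.any():
                repl[clash] = np.asarray(alphabet)[rng.integers(0, len(alphabet),
                                                                int(clash.sum()))]
                clash = m & (repl == raster)
            raster = np.where(m, repl, raster)
        return raster

    for year in IMPERVIOUSNESS_YEARS:
        imperv = np.where(base == 1, rng.uniform(51, 100, (rows, cols)), 0.0)
        stack.add("imperviousness", year, contaminate(imperv))
    for year in TREE_DENSITY_YEARS:
        tree = np.zeros((rows, cols))
        forest = np.isin(base, (5, 6))
        tree[forest] = rng.uniform(76, 100, int(forest.sum()))
        shrub = base == 4
        tree[shrub] = rng.uniform(1, 29, int(shrub.sum()))
        stack.add("tree_density", year, contaminate(tree))
    clc_lut = np.zeros(19, int)
    n2k_lut = np.zeros(19, int)
    ft_lut = np.zeros(19, int)
    for code, (ck, nk, fk) in _CLASS_TO_PRODUCT.items():
        clc_lut[code] = CLC_CODES[ck]
        n2k_lut[code] = N2K_CODES[nk]
        ft_lut[code] = FOREST_TYPE_CODES[fk]
    for year in FOREST_TYPE_YEARS:
        stack.add("forest_type", year,
                  disagree(ft_lut[base], sorted(FOREST_TYPE_CODES.values())))
    for year in CATEGORICAL_YEARS:
        stack.add("clc_code", year, disagree(clc_lut[base], sorted(set(CLC_CODES.values()))))
        stack.add("n2k_code", year, disagree(n2k_lut[base], sorted(set(N2K_CODES.values()))))
    return stack
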