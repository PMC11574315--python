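# Methods

This note documents the models, parameter choices and numerical
conventions of the package, and what the synthetic experiments do and do
not demonstrate.

## Weekly temporal encoding

A pixel-year is a set of dated clear-sky observations of six reflectance
bands. The encoder assigns each observation to week
`w = floor((doy − 1)/7)`, with days 365/366 folded into week 51 so that
exactly 52 slots exist; all clear observations of a week are averaged
per band, and empty weeks hold exactly 0. Nine bands are encoded: the
six reflectances and NDVI = (NIR−R)/(NIR+R), NDWI = (G−NIR)/(G+NIR)
(the green/NIR form, which is the one consistent with a
permanent-water rule of the type NDWI₁₀ > 0.3), and
SAVI = (NIR−R)(1+L)/(NIR+R+L) with the canonical soil factor L = 0.5.
Zero denominators define the index as 0 with a flag. Feature size is
52 × 9 = 468 per sample.

Two augmentations act on the raw series before encoding, once per
sample per epoch:

* **random observation selection** — a keep fraction is drawn uniformly
  from [0.1, 1.0] and each observation is kept i.i.d. with that
  probability (at least one observation survives). The lower bound 0.1
  is chosen so that a dense year (~30 obs) thinned at the minimum
  matches the sparsest years the pipeline must map (~3–8 obs).
* **random day shifting** — one integer offset drawn uniformly from
  [−10, +10] days is added to all dates; observations leaving [1, 365]
  are dropped. A single shared offset models a phenological shift of
  the whole season, which is the stated purpose of the augmentation;
  per-observation jitter would instead model geolocation/timing noise.

## Classifier

The classifier is a 1-D CNN over the week axis, implemented in NumPy
(im2col convolutions with same-padding, ReLU, max-pool, dense layers,
dropout, softmax; Adam; class-weighted cross-entropy with
inverse-frequency weights, since sampling caps differ between classes).
Missing weeks enter as the encoder's zeros without a mask channel. All
stochastic elements (initialisation, batch order, dropout,
augmentation, per-epoch year draw) flow from one seeded generator, so
training is bit-reproducible on one device.

The default architecture is 3 conv blocks (64/128/128 filters, kernel
5 weeks, pool 2), dense 256, dropout 0.3, lr 1e-3, batch 256, 30
epochs; every value is configurable. The analysis scripts and tests use
a reduced configuration (2 blocks of 24/48 filters, dense 64, dropout
0.2, 64 epochs, batch 128), which the experiments below show is ample
for the synthetic scenes while keeping single-CPU runtimes in minutes;
the stated problem sizes (60×60 training scene, 40×40 evaluation scene,
6 years, ~120 invariant / ~150 crop samples per class) are likewise the
package's default study conditions.

Hierarchy: the Level-1 model has 8 classes; pixels predicted Wetland or
Cropland & Grassland are refined by two specialist models (3 and 9
classes). Two specialists — rather than one 18-class head — mirror the
two subdivided branches of the legend; the single-head alternative
would be a one-line change. Samples whose label is invariant across the
reference years carry one series per year and a uniformly drawn year is
used each epoch; crop samples carry only their labeled year. Crop
parcel samples additionally support the Level-1 model under their
parent class, so grassland's distinct phenology is represented inside
the Cropland & Grassland stratum.

## Rule-based reference sampling

The ten invariant-class rules are transcribed with their printed
thresholds, years and strictness (e.g. Built-up: all 24 surrounding
pixels > 20% imperviousness and the centre > 50% in all of
2006/2009/2012/2015/2018; Coniferous: 5×5-window CLC and forest-type
agreement plus tree density > 75%). Conditions combine with AND;
focal conditions use an ALL quantifier over the 5×5 window (or the
24-pixel ring), implemented as a minimum filter with constant-False
padding so windows touching the raster edge or nodata are ineligible.
Index percentiles use the linear-interpolation definition. Where the
source phrasing is ambiguous ("both CLC and N2K contain one of these
classes") the stricter same-subclass-agreement reading is implemented;
the marsh rule, phrased as two separate per-product criteria, is read
as independent set membership per product. Sampling draws
min(cap, eligible) pixels uniformly without replacement (caps: 10,000
per invariant class, 50,000 per crop class per labeled year; the
scene-sized analyses use proportionally smaller caps).

## Post-classification filters

* **Spatial majority (3×3, both levels).** Fires only when the centre
  differs from *all eight* neighbours (the isolated-pixel reading of
  the trigger), replacing it by the neighbours' modal class; evaluated
  on a frozen copy (no cascading), borders unchanged, ties broken
  toward the smallest class code for determinism.
* **Temporal (3-year window, Level 1).** Slides backward from the last
  year; (X, Y, X) with Y ≠ X becomes (X, X, X), and updates are visible
  to subsequent (earlier) windows, as a backward running order implies.
  First and last years are never modified.
* **Spatio-temporal (3×3×3 cube, Level 2).** Backward over years with
  stride-1 overlapping patches: if one class fills a 3×3 patch in both
  neighbouring years and ≥ 7 of the 9 centre-year pixels already agree,
  the centre patch converts. Within one year, conditions are evaluated
  on a frozen copy of that year; overlapping triggers cannot conflict
  because the neighbour-year patches pin the class. Alternating crop
  sequences in heterogeneous patches are untouched, which is why
  Level-2 maps get this filter instead of the plain temporal one.
  Windows containing nodata are skipped.

All three filters are verified against exhaustive brute-force oracles
on random label cubes (exact agreement).

## Stratified accuracy and area estimation

With map classes as strata, weights W_i = A_i/A_total and cell
proportions p̂_ij = W_i n_ij/n_i·: OA = Σ p̂_ii, UA_i = n_ii/n_i·,
PA_j = p̂_jj/p̂_·j, and error-adjusted areas Â_j = A_total Σ_i W_i
n_ij/n_i· with the standard stratified standard errors; intervals are
normal-approximation 95% (z = 1.96), matching the ± convention of
area-accuracy tables. Estimated areas sum to the total mapped area by
construction. The implementation reproduces an independent
exact-fraction hand computation on a 3-class matrix to machine
precision, and its 95% area CIs attain 93–95% empirical coverage over
500 repeated stratified samplings of a fixed finite population (250
points per stratum; at much smaller allocations the normal
approximation is visibly liberal). Validation points whose mapped class
is nodata are dropped with a count. Per-class F1 uses the standard form
TP/(TP + 0.5(FP+FN)), verified against the harmonic-mean identity
2PR/(P+R).

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
not radiometric realism:

* **Phenology.** Per class, reflectance follows
  `base_b + amplitude_b · s(t)` with the double-logistic seasonal term
  `s(t) = σ(r_up(t−greenup)) + σ(−r_down(t−senescence)) − 1`, additive
  Gaussian noise (default σ = 0.02; 0.005 for water, whose indices are
  extremely sensitive to noise at small denominators), clipped to
  [0, 1]. The 18 default parameter sets differ in dormant/peak spectra
  and in sowing/harvest timing (winter vs spring cereals, late maize
  and root crops, evergreen conifers, dark flat extracted peat, etc.).
  Indices are always computed downstream, never simulated directly.
* **Acquisition.** Clear-sky dates per year follow a Poisson process
  (expected ~8/yr before 2015, ~30/yr after — the Landsat-only vs
  two-constellation eras) thinned by a mild summer-biased weekly
  weighting; all returned dates are flagged clear.
* **Landscape.** Patches are Voronoi cells of jittered-grid seeds
  (compact, field-like, similar sizes), classes allocated round-robin
  so all 18 occur. Non-crop classes persist; crop patches rotate as
  units through a configurable transition matrix (default: stay
  probability 0.55); unexploited-bog pixels convert permanently to
  exploited at a configured rate per year, preferring the frontier of
  existing extraction, capped with a warning when bog runs out. A small
  per-pixel-year season jitter (σ = 3 days) perturbs green-up and
  senescence jointly.
* **Reference products.** Derived from the truth map with configurable
  contamination (continuous layers) and disagreement (categorical
  layers); the CLC-like product does not separate the two peat-bog
  states, the N2K-like product does — mirroring real product semantics.
  The code dictionaries are package constants, not the real products'
  code lists.

Separability is a documented guarantee, not an accident: with default
phenologies and ≥ 20 clear obs/yr, a gap-aware nearest-centroid
classifier (centroids over filled weeks, distances restricted to the
sample's observed weeks — a plain Euclidean distance on zero-filled
encodings measures acquisition-gap overlap rather than class identity)
recovers ≥ 95% of samples. Passing recovery tests therefore shows that
the pipeline's machinery is correct and transfers across observation
densities; it does not show that real Baltic land covers are this
separable, and the near-perfect synthetic accuracies should not be read
as expected real-world performance (real maps of this type reach
overall accuracies around 0.8).

## Degenerate inputs and conventions

Nodata code is 0 everywhere (label rasters stay byte-typed). Pixel
centres sit at origin + (i + 0.5)·30 m. Tiles are half-open on their
max edges, so tilings partition the plane. Empty observation series
encode to the all-zero matrix and are valid classifier inputs. Pixels
with no clear observation get NaN spectral-temporal metrics and are
ineligible for every rule. Series CRS handling is metadata-only; a
mismatched CRS raises rather than reprojecting.

## Known limitations

* The NumPy CNN is single-device and modest in capacity; it is meant
  for scene-scale experiments, not continental tiling.
* The generator has no cloud-shadow geometry, topography, sensor
  differences or mixed pixels; class difficulty is controlled entirely
  by the phenology table and noise level.
* Rule thresholds are transcribed for the synthetic product semantics;
  applying them to real CLMS layers would require the real code lists.
* The spatio-temporal filter's "two surrounding years" is read as
  t−1/t+1; the temporal filter is not applied to Level-2 maps by
  design, so isolated one-year errors in non-crop Level-2 classes can
  survive where patches are heterogeneous.
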