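"""1-D temporal-convolution classifier and the hierarchical prediction scheme.

The network convolves along the 52-week axis of the encoded sample
(convolution -> ReLU -> max-pool blocks, then dense layers and a softmax
head), so filters learn local phenological shapes irrespective of their
absolute calendar position within the receptive field. Missing weeks are
fed as the encoder's zeros without a mask channel. Training minimises
class-weighted cross-entropy with Adam, applies the two augmentations
(random observation selection, random day shifting) on the fly by
re-encoding each series every epoch, and draws a random year per epoch
for samples whose label is invariant across years.

Hierarchy: a Level-1 model separates the eight general classes; pixels
mapped as Wetland or Cropland & Grassland are refined by two specialist
Level-2 models into the final 18-class legend.

The implementation is plain NumPy (im2col convolutions); it is exactly
reproducible given (spec, data, seed) on one device.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import (
    N_BANDS,
    N_WEEKS,
    ObservationSeries,
    augment_random_day_shift,
    augment_random_obs_selection,
    encode_weekly,
)
from .legend import DEFAULT_LEGEND, L1_CROP_GRASS, L1_WETLAND, LEVEL2_TO_LEVEL1


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training configuration (all values configurable)."""

    n_classes: int
    conv_blocks: tuple[tuple[int, int, int], ...] = ((64, 5, 2), (128, 5, 2), (128, 5, 2))
    dense: tuple[int, ...] = (256,)
    dropout: float = 0.3
    epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-3
    class_weighting: bool = True
    keep_fraction_range: tuple[float, float] = (0.1, 1.0)
    max_shift_days: int = 10
    input_shape: tuple[int, int] = (N_WEEKS, N_BANDS)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for f, k, p in self.conv_blocks:
            if not (0 < k <= self.input_shape[0]) or f <= 0 or p <= 0:
                raise ValueError("invalid conv block parameters")


@dataclass
class TrainingSample:
    """One training pixel: a label plus its series, possibly for several years.

    Invariant samples carry one series per reference year and a random
    year is drawn each epoch; crop samples carry their labeled year only.
    """

    label: int
    series_by_year: dict[int, ObservationSeries]


# ---------------------------------------------------------------------------
# layers


def _conv_forward(x, w, b, k):
    # x: (N, L, C); w: (k*C, F); same padding
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, k - 1 - pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (N, L, C, k)
    cols = win.transpose(0, 1, 3, 2).reshape(x.shape[0], x.shape[1], -1)  # (N, L, k*C)
    return cols @ w + b, cols


def _conv_backward(dout, cols, w, x_shape, k):
    # dout: (N, L, F)
    n, length, c = x_shape
    dw = np.tensordot(cols, dout, axes=([0, 1], [0, 1]))  # (k*C, F)
    db = dout.sum(axis=(0, 1))
    dcols = dout @ w.T  # (N, L, k*C)
    dcols = dcols.reshape(n, length, k, c)
    pad = (k - 1) // 2
    dxp = np.zeros((n, length + k - 1, c))
    for i in range(k):
        dxp[:, i:i + length] += dcols[:, :, i]
    return dxp[:, pad:pad + length], dw, db


def _pool_forward(x, p):
    n, length, c = x.shape
    lp = length // p
    xv = x[:, : lp * p].reshape(n, lp, p, c)
    idx = xv.argmax(axis=2)
    out = xv.max(axis=2)
    return out, (idx, x.shape, p)


def _pool_backward(dout, cache):
    idx, (n, length, c), p = cache
    lp = dout.shape[1]
    dx = np.zeros((n, lp, p, c))
    ii, jj, kk = np.ix_(np.arange(n), np.arange(lp), np.arange(c))
    dx[ii, jj, idx, kk] = dout
    full = np.zeros((n, length, c))
    full[:, : lp * p] = dx.reshape(n, lp * p, c)
    return full


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class TemporalCNN:
    """Fitted 1-D CNN; holds the spec, the class list and the weights."""

    def __init__(self, spec: ModelSpec, classes: np.ndarray, seed: int):
        self.spec = spec
        self.classes_ = np.asarray(classes)
        if len(self.classes_) != spec.n_classes:
            raise ValueError(
                f"spec expects {spec.n_classes} classes, data has {len(self.classes_)}"
            )
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: list[np.ndarray] = []
        length, channels = spec.input_shape
        for f, k, p in spec.conv_blocks:
            scale = np.sqrt(2.0 / (k * channels))
            self.params += [rng.normal(0, scale, (k * channels, f)), np.zeros(f)]
            length, channels = length // p, f
        width = length * channels
        for h in spec.dense:
            self.params += [rng.normal(0, np.sqrt(2.0 / width), (width, h)), np.zeros(h)]
            width = h
        self.params += [
            rng.normal(0, np.sqrt(1.0 / width), (width, spec.n_classes)),
            np.zeros(spec.n_classes),
        ]

    # forward returning caches for backprop
    def _forward(self, x, rng=None):
        spec = self.spec
        caches = []
        h = x
        pi = 0
        for f, k, p in spec.conv_blocks:
            w, b = self.params[pi], self.params[pi + 1]
            z, cols = _conv_forward(h, w, b, k)
            a = np.maximum(z, 0)
            pooled, pcache = _pool_forward(a, p)
            caches.append(("conv", cols, w, h.shape, k, z, pcache))
            h = pooled
            pi += 2
        flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        for _ in spec.dense:
            w, b = self.params[pi], self.params[pi + 1]
            z = h @ w + b
            a = np.maximum(z, 0)
            mask = None
            if rng is not None and spec.dropout > 0:
                mask = (rng.random(a.shape) >= spec.dropout) / (1 - spec.dropout)
                a = a * mask
            caches.append(("dense", h, w, z, mask))
            h = a
            pi += 2
        w, b = self.params[pi], self.params[pi + 1]
        logits = h @ w + b
        caches.append(("head", h, w, flat_shape))
        return logits, caches

    def _backward(self, dlogits, caches):
        grads = [np.zeros_like(p) for p in self.params]
        pi = len(self.params) - 2
        kind, h, w, flat_shape = caches[-1]
        grads[pi] = h.T @ dlogits
        grads[pi + 1] = dlogits.sum(0)
        dh = dlogits @ w.T
        pi -= 2
        for cache in reversed(caches[:-1]):
            if cache[0] == "dense":
                _, hin, w, z, mask = cache
                if mask is not None:
                    dh = dh * mask
                dz = dh * (z > 0)
                grads[pi] = hin.T @ dz
                grads[pi + 1] = dz.sum(0)
                dh = dz @ w.T
                pi -= 2
            else:
                _, cols, w, x_shape, k, z, pcache = cache
                if dh.ndim == 2:
                    dh = dh.reshape(flat_shape)
                da = _pool_backward(dh, pcache)
                dz = da * (z > 0)
                dh, grads[pi], grads[pi + 1] = _conv_backward(dz, cols, w, x_shape, k)
                pi -= 2
        return grads

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"sample shape {X.shape[1:]} does not match spec {self.spec.input_shape}"
            )
        if not np.isfinite(X).all():
            raise ValueError("NaN/inf in features")
        out = np.empty((X.shape[0], self.spec.n_classes))
        for i in range(0, X.shape[0], 1024):
            logits, _ = self._forward(X[i:i + 1024])
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out[i:i + 1024] = e / e.sum(axis=1, keepdims=True)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def _class_weights(y_idx, n_classes, enabled):
    if not enabled:
        return np.ones(n_classes)
    counts = np.bincount(y_idx, minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = counts.sum() / (n_classes * counts)
    return w


def train(
    spec: ModelSpec,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    samples: list[TrainingSample] | None = None,
    seed: int = 0,
) -> TemporalCNN:
    """Fit the network on encoded arrays (X, y) or raw `samples`.

    With `samples`, each epoch draws a year per invariant sample, applies
    both augmentations to the series, and re-encodes — so the model sees
    a different realisation of each pixel every epoch.
    """
    rng = np.random.default_rng(seed)
    if samples is not None:
        labels = np.array([s.label for s in samples])
    else:
        if X is None or y is None:
            raise ValueError("provide (X, y) or samples")
        X = np.asarray(X, float)
        if not np.isfinite(X).all():
            raise ValueError("NaN/inf in features")
        labels = np.asarray(y)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    model = TemporalCNN(spec, classes, seed=int(rng.integers(2**31)))
    index_of = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([index_of[c] for c in labels])
    weights = _class_weights(y_idx, spec.n_classes, spec.class_weighting)
    opt = _Adam(model.params, spec.learning_rate)

    n = len(labels)
    for _ in range(spec.epochs):
        if samples is not None:
            Xe = np.empty((n, *spec.input_shape))
            for i, s in enumerate(samples):
                years = sorted(s.series_by_year)
                year = years[rng.integers(len(years))] if len(years) > 1 else years[0]
                ser = s.series_by_year[year]
                ser = augment_random_obs_selection(ser, spec.keep_fraction_range, rng)
                ser = augment_random_day_shift(ser, spec.max_shift_days, rng)
                Xe[i] = encode_weekly(ser).matrix
        else:
            Xe = X
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            xb, yb = Xe[idx], y_idx[idx]
            logits, caches = model._forward(xb, rng=rng)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            p = e / e.sum(axis=1, keepdims=True)
            wb = weights[yb]
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits *= (wb / wb.sum())[:, None]
            grads = model._backward(dlogits, caches)
            opt.step(model.params, grads)
    return model


# ---------------------------------------------------------------------------
# hierarchy


@dataclass
class HierarchySpec:
    """Level-1 model plus the two Level-2 specialists and the code mapping."""

    level1: TemporalCNN  # classes: Level-1 codes 1..8
    level2_wetland: TemporalCNN  # classes: 7, 8, 9
    level2_crop: TemporalCNN  # classes: 10..18

    def __post_init__(self) -> None:
        mapped = set()
        for e in DEFAULT_LEGEND.entries:
            mapped.add(e.code)
        if mapped != set(range(1, 19)):
            raise ValueError("legend mapping must cover codes 1..18")


def hierarchical_predict(h: HierarchySpec, X: np.ndarray) -> np.ndarray:
    """Final 18-class codes for encoded samples X of shape (n, 52, 9).

    Level-1 argmax first; the six non-subdivided classes pass through to
    codes 1..6, Wetland pixels get the wetland specialist's argmax
    (codes 7..9) and Cropland & Grassland pixels the crop specialist's
    (codes 10..18).
    """
    X = np.asarray(X, float)
    l1 = h.level1.predict(X)
    valid = set(LEVEL2_TO_LEVEL1.values())
    unknown = set(np.unique(l1)) - valid
    if unknown:
        raise ValueError(f"Level-1 model produced unmapped codes {sorted(unknown)}")
    out = np.asarray(l1).copy()
    wet = l1 == L1_WETLAND
    if wet.any():
        out[wet] = h.level2_wetland.predict(X[wet])
    crop = l1 == L1_CROP_GRASS
    if crop.any():
        out[crop] = h.level2_crop.predict(X[crop])
    return out
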