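"""Accuracy assessment and stratified area estimation.

Maps are scored against reference points with an error matrix n_ij (map
class i in rows, reference class j in columns). Per-class F1 uses the
standard form TP / (TP + 0.5 (FP + FN)). Area-weighted ("good
practices") estimation treats the map classes as strata with weights
W_i = A_i / A_total and reports, with normal-approximation 95% CIs:

  p_hat_ij = W_i n_ij / n_i.          (cell area proportions)
  OA       = sum_i p_hat_ii
  UA_i     = n_ii / n_i.              PA_j = p_hat_jj / p_hat_.j
  A_hat_j  = A_total sum_i p_hat_ij   (error-adjusted class area)

with the stratified standard errors for each quantity. The estimated
areas always sum to the total mapped area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cube import LabelCube

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ErrorMatrix:
    classes: list[int]
    counts: np.ndarray  # (k, k): rows = map class, cols = reference class
    mapped_areas: np.ndarray  # per map class, km^2

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        self.mapped_areas = np.asarray(self.mapped_areas, float)
        k = len(self.classes)
        if self.counts.shape != (k, k) or self.mapped_areas.shape != (k,):
            raise ValueError("counts must be square and areas per map class")
        if (self.counts < 0).any() or (self.mapped_areas < 0).any():
            raise ValueError("counts and areas must be nonnegative")

    @property
    def total_area(self) -> float:
        return float(self.mapped_areas.sum())


def build_error_matrix(
    reference: pd.DataFrame,
    predicted: np.ndarray,
    mapped_areas: dict[int, float],
    nodata: int = 0,
) -> ErrorMatrix:
    """Tally (map, reference) pairs for points carried as (row, col, class_code)."""
    classes = sorted(mapped_areas)
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k))
    skipped = 0
    for _, p in reference.iterrows():
        m = int(predicted[int(p["row"]), int(p["col"])])
        ref = int(p["class_code"])
        if m == nodata or m not in idx or ref not in idx:
            skipped += 1
            continue
        counts[idx[m], idx[ref]] += 1
    if counts.sum() == 0:
        raise ValueError("no usable reference points fall on the map")
    em = ErrorMatrix(classes, counts, np.array([mapped_areas[c] for c in classes]))
    em.skipped_points = skipped
    return em


def f1_scores(matrix: ErrorMatrix) -> dict[int, float]:
    """Per-class F1 = TP / (TP + 0.5 (FP + FN)); absent classes -> NaN."""
    out = {}
    n = matrix.counts
    for i, c in enumerate(matrix.classes):
        tp = n[i, i]
        fp = n[i, :].sum() - tp
        fn = n[:, i].sum() - tp
        out[c] = float("nan") if tp + fp + fn == 0 else tp / (tp + 0.5 * (fp + fn))
    return out


@dataclass
class AccuracyReport:
    classes: list[int]
    mapped_area: np.ndarray
    estimated_area: np.ndarray
    estimated_area_ci: np.ndarray  # 95% half-widths, km^2
    producers: np.ndarray
    producers_ci: np.ndarray
    users: np.ndarray
    users_ci: np.ndarray
    overall_accuracy: float
    overall_accuracy_ci: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_code": self.classes,
                "mapped_area_km2": self.mapped_area,
                "estimated_area_km2": self.estimated_area,
                "estimated_area_ci95_km2": self.estimated_area_ci,
                "producers_accuracy": self.producers,
                "producers_accuracy_ci95": self.producers_ci,
                "users_accuracy": self.users,
                "users_accuracy_ci95": self.users_ci,
            }
        )


def olofsson_estimates(matrix: ErrorMatrix, confidence: float = 0.95) -> AccuracyReport:
    """Stratified accuracy and error-adjusted area estimates with CIs."""
    if abs(confidence - 0.95) > 1e-12:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + confidence / 2))
    else:
        z = Z95
    n = matrix.counts
    k = len(matrix.classes)
    n_i = n.sum(axis=1)
    empty = [matrix.classes[i] for i in range(k) if n_i[i] == 0]
    if empty:
        raise ValueError(f"strata with zero samples: {empty}")
    A = matrix.mapped_areas
    A_tot = matrix.total_area
    W = A / A_tot
    p = W[:, None] * n / n_i[:, None]  # p_hat_ij

    oa = float(np.trace(p))
    ua = np.diag(n) / n_i
    se_oa = np.sqrt(np.sum(W**2 * ua * (1 - ua) / np.maximum(n_i - 1, 1)))

    se_ua = np.sqrt(ua * (1 - ua) / np.maximum(n_i - 1, 1))

    p_dot_j = p.sum(axis=0)
    pa = np.where(p_dot_j > 0, np.diag(p) / np.where(p_dot_j > 0, p_dot_j, 1), np.nan)

    # PA standard error (stratified formula); N_i taken as mapped areas
    N = A
    N_hat_j = (N[:, None] * n / n_i[:, None]).sum(axis=0)
    se_pa = np.full(k, np.nan)
    for j in range(k):
        if p_dot_j[j] <= 0:
            continue
        term1 = (
            N[j] ** 2 * (1 - pa[j]) ** 2 * ua[j] * (1 - ua[j])
            / max(n_i[j] - 1, 1)
        )
        term2 = 0.0
        for i in range(k):
            if i == j:
                continue
            pij = n[i, j] / n_i[i]
            term2 += N[i] ** 2 * pij * (1 - pij) / max(n_i[i] - 1, 1)
        se_pa[j] = np.sqrt(term1 + pa[j] ** 2 * term2) / N_hat_j[j]

    est_area = A_tot * p_dot_j
    se_p_dot_j = np.sqrt(
        np.sum(
            W[:, None] ** 2
            * (n / n_i[:, None])
            * (1 - n / n_i[:, None])
            / np.maximum(n_i - 1, 1)[:, None],
            axis=0,
        )
    )
    se_area = A_tot * se_p_dot_j

    return AccuracyReport(
        classes=list(matrix.classes),
        mapped_area=A,
        estimated_area=est_area,
        estimated_area_ci=z * se_area,
        producers=pa,
        producers_ci=z * se_pa,
        users=ua,
        users_ci=z * se_ua,
        overall_accuracy=oa,
        overall_accuracy_ci=float(z * se_oa),
    )


def class_area_series(cube: LabelCube, class_code: int) -> pd.Series:
    """Mapped area (km^2) of one class per year: pixel count x pixel area."""
    px_km2 = (cube.transform.pixel_size / 1000.0) ** 2
    counts = cube.class_pixel_counts(class_code)
    return pd.Series({y: c * px_km2 for y, c in counts.items()}, name=f"class_{class_code}")


def compare_area_series(
    map_areas: pd.DataFrame, statistics: pd.DataFrame
) -> pd.DataFrame:
    """Map-minus-statistics differences per class and year (no smoothing).

    Both tables have columns (class_code, year, area_km2); only shared
    (class, year) pairs are compared.
    """
    merged = map_areas.merge(
        statistics, on=["class_code", "year"], suffixes=("_map", "_stats")
    )
    if merged.empty:
        raise ValueError("map areas and statistics share no (class, year) pairs")
    merged["difference_km2"] = merged["area_km2_map"] - merged["area_km2_stats"]
    merged["relative_error"] = merged["difference_km2"] / merged["area_km2_stats"]
    return merged
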