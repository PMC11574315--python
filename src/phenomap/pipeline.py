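"""End-to-end orchestration: simulate -> sample -> encode -> train -> predict
-> postprocess -> validate.

Each stage is a pure function over an explicit state dictionary, and
`run_stage` wraps them with artifact persistence and a JSON manifest
(seed, config hash, counters), so a stage rerun with the same manifest
reproduces its outputs. A single global seed fans out to per-stage seeds
derived from a hash of the stage name, making stages independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import postprocess as pp
from .classifier import HierarchySpec, ModelSpec, TrainingSample, hierarchical_predict, train
from .cube import LabelCube
from .encoding import encode_weekly
from .legend import (
    CROP_GRASS_CODES,
    DEFAULT_LEGEND,
    L1_CROP_GRASS,
    LEVEL1_NAMES,
    LEVEL2_TO_LEVEL1,
    WETLAND_CODES,
)
from .sampling import add_stm_products, builtin_rules, evaluate_rule, sample_points
from .synthetic import Scene, SceneConfig, simulate_landscape, simulate_reference_products
from .validation import build_error_matrix, f1_scores, olofsson_estimates

STAGES = ("simulate", "sample", "encode", "train", "predict", "postprocess", "validate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed: hash of stage name mixed with the global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Study conditions for one pipeline run (defaults = the package's own)."""

    train_scene: SceneConfig = field(
        default_factory=lambda: SceneConfig(shape=(60, 60), n_patches=49, seed=11)
    )
    eval_scene: SceneConfig = field(default_factory=lambda: SceneConfig(seed=23))
    invariant_cap: int = 120  # training pixels per invariant class (scene-sized)
    crop_cap: int = 150  # training pixels per crop class per labeled year
    crop_label_years: int = 2  # most recent years with crop labels
    conv_blocks: tuple = ((24, 5, 2), (48, 5, 2))
    dense: tuple = (64,)
    dropout: float = 0.2
    epochs: int = 64
    batch_size: int = 128
    learning_rate: float = 1e-3
    keep_fraction_range: tuple = (0.1, 1.0)
    max_shift_days: int = 10
    apply_filters: bool = True
    validation_points_per_class: int = 60
    seed: int = 0

    def model_spec(self, n_classes: int) -> ModelSpec:
        return ModelSpec(
            n_classes=n_classes,
            conv_blocks=self.conv_blocks,
            dense=self.dense,
            dropout=self.dropout,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            keep_fraction_range=self.keep_fraction_range,
            max_shift_days=self.max_shift_days,
        )


def describe_legend() -> str:
    """Human-readable legend listing: 18 codes, names, Level-1 grouping."""
    lines = []
    for e in DEFAULT_LEGEND.entries:
        lines.append(f"{e.code:>2}  {e.name:<22} (Level-1: {LEVEL1_NAMES[e.parent_level1_code]})")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# stage computations (pure functions over the state dict)


def build_training_samples(
    scene: Scene, config: PipelineConfig, rng: np.random.Generator
):
    """Mine invariant-class points with the ten rules; sample crop points
    from parcel-labeled recent years. Returns (level1, wetland, crop) sets."""
    stack = simulate_reference_products(scene.truth, rng)
    add_stm_products(stack, scene.series, scene.truth.shape)

    level1: list[TrainingSample] = []
    wetland: list[TrainingSample] = []
    rule_counts = {}
    for rule in builtin_rules():
        mask = evaluate_rule(stack, rule)
        pts = sample_points(mask, config.invariant_cap, rng)
        rule_counts[rule.name] = len(pts)
        for r, c in pts:
            series = scene.series[(int(r), int(c))]
            l1_code = (
                rule.target_code if rule.target_level == 1
                else LEVEL2_TO_LEVEL1[rule.target_code]
            )
            level1.append(TrainingSample(label=l1_code, series_by_year=series))
            if rule.target_level == 2 and rule.target_code in WETLAND_CODES:
                wetland.append(TrainingSample(label=rule.target_code,
                                              series_by_year=series))

    crop: list[TrainingSample] = []
    label_years = scene.truth.years[-config.crop_label_years:]
    for code in CROP_GRASS_CODES:
        for year in label_years:
            t = scene.truth.year_index(year)
            px = np.argwhere(scene.truth.data[t] == code)
            if len(px) == 0:
                continue
            take = min(config.crop_cap, len(px))
            chosen = px[rng.choice(len(px), size=take, replace=False)]
            for r, c in chosen:
                s = scene.series[(int(r), int(c))][year]
                crop.append(TrainingSample(label=code, series_by_year={year: s}))
                # parcel points also support Level 1 under their parent class
                level1.append(TrainingSample(label=L1_CROP_GRASS,
                                             series_by_year={year: s}))
    return level1, wetland, crop, rule_counts


def encode_scene(scene: Scene, year: int) -> np.ndarray:
    """Encode every pixel of one scene year, row-major, into (n, 52, 9)."""
    rows, cols = scene.truth.shape
    X = np.empty((rows * cols, 52, 9))
    i = 0
    for r in range(rows):
        for c in range(cols):
            X[i] = encode_weekly(scene.series[(r, c)][year]).matrix
            i += 1
    return X


def train_hierarchy(
    level1, wetland, crop, config: PipelineConfig, seed: int
) -> HierarchySpec:
    m1 = train(config.model_spec(8), samples=level1, seed=stage_seed(seed, "train-l1"))
    mw = train(config.model_spec(3), samples=wetland, seed=stage_seed(seed, "train-wet"))
    mc = train(config.model_spec(9), samples=crop, seed=stage_seed(seed, "train-crop"))
    return HierarchySpec(level1=m1, level2_wetland=mw, level2_crop=mc)


def predict_scene(hier: HierarchySpec, scene: Scene) -> LabelCube:
    """Hierarchical per-pixel prediction for every scene year."""
    rows, cols = scene.truth.shape
    data = np.zeros_like(scene.truth.data)
    for t, year in enumerate(scene.truth.years):
        X = encode_scene(scene, year)
        data[t] = hierarchical_predict(hier, X).reshape(rows, cols)
    return LabelCube(list(scene.truth.years), data, scene.truth.transform,
                     scene.truth.crs)


def aggregate_level1(cube: LabelCube) -> LabelCube:
    lut = np.zeros(19, int)
    for code, l1 in LEVEL2_TO_LEVEL1.items():
        lut[code] = l1
    return LabelCube(list(cube.years), lut[cube.data], cube.transform, cube.crs)


def evaluate_predictions(pred: LabelCube, truth: LabelCube) -> dict:
    """Pixel-year overall accuracy and per-class F1 against the truth cube."""
    y_true = truth.data.ravel()
    y_pred = pred.data.ravel()
    ok = y_true != truth.nodata
    oa = float((y_true[ok] == y_pred[ok]).mean())
    classes = sorted(set(np.unique(y_true[ok])))
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k))
    for tr, pr in zip(y_true[ok], y_pred[ok]):
        if pr in idx:
            counts[idx[pr], idx[tr]] += 1
    from .validation import ErrorMatrix

    em = ErrorMatrix(classes, counts, np.ones(k))
    f1 = f1_scores(em)
    return {"overall_accuracy": oa, "f1": f1}


def validate_stratified(
    pred_year: np.ndarray,
    truth_year: np.ndarray,
    pixel_size_m: float,
    n_per_class: int,
    rng: np.random.Generator,
):
    """Stratified validation sample from the map, scored with area estimation."""
    px_km2 = (pixel_size_m / 1000.0) ** 2
    classes = [c for c in np.unique(pred_year) if c != 0]
    mapped_areas = {int(c): float((pred_year == c).sum() * px_km2) for c in classes}
    rows_ = []
    for c in classes:
        px = np.argwhere(pred_year == c)
        take = min(n_per_class, len(px))
        chosen = px[rng.choice(len(px), size=take, replace=False)]
        for r, cc in chosen:
            rows_.append((int(r), int(cc), int(truth_year[r, cc])))
    ref = pd.DataFrame(rows_, columns=["row", "col", "class_code"])
    em = build_error_matrix(ref, pred_year, mapped_areas)
    return em, olofsson_estimates(em)


# ---------------------------------------------------------------------------
# managed stage runner


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_stage(name: str, config: PipelineConfig, workdir: str | Path) -> dict:
    """Run one named stage, persisting state and a JSON manifest in `workdir`."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; valid: {STAGES}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    state_path = workdir / "state.pkl"
    state = pickle.loads(state_path.read_bytes()) if state_path.exists() else {}

    def need(key: str, produced_by: str):
        if key not in state:
            raise RuntimeError(
                f"stage {name!r} needs {key!r}; run stage {produced_by!r} first"
            )
        return state[key]

    seed = stage_seed(config.seed, name)
    rng = np.random.default_rng(seed)
    counters: dict = {}

    if name == "simulate":
        state["train_scene"] = simulate_landscape(config.train_scene)
        state["eval_scene"] = simulate_landscape(config.eval_scene)
        counters["pixels"] = int(np.prod(config.train_scene.shape))
    elif name == "sample":
        scene = need("train_scene", "simulate")
        l1, wet, crop, rule_counts = build_training_samples(scene, config, rng)
        state.update(l1_samples=l1, wet_samples=wet, crop_samples=crop)
        counters.update(rule_counts)
        counters["crop_samples"] = len(crop)
    elif name == "encode":
        scene = need("eval_scene", "simulate")
        state["encoded"] = {y: encode_scene(scene, y) for y in scene.truth.years}
        counters["samples"] = sum(len(v) for v in state["encoded"].values())
    elif name == "train":
        l1 = need("l1_samples", "sample")
        state["hierarchy"] = train_hierarchy(
            l1, state["wet_samples"], state["crop_samples"], config, config.seed
        )
        counters["l1_samples"] = len(l1)
    elif name == "predict":
        hier = need("hierarchy", "train")
        scene = need("eval_scene", "simulate")
        state["prediction"] = predict_scene(hier, scene)
        counters["pixel_years"] = int(state["prediction"].data.size)
    elif name == "postprocess":
        cube = need("prediction", "predict")
        if config.apply_filters:
            filtered = pp.level2_bundle(cube)
            counters["pixels_changed"] = int((filtered.data != cube.data).sum())
            state["filtered"] = filtered
        else:
            state["filtered"] = cube.copy()
    elif name == "validate":
        cube = need("filtered", "postprocess")
        scene = need("eval_scene", "simulate")
        metrics = evaluate_predictions(cube, scene.truth)
        year = scene.truth.years[-1]
        em, report = validate_stratified(
            cube.grid(year), scene.truth.grid(year),
            scene.truth.transform.pixel_size, config.validation_points_per_class, rng,
        )
        state["metrics"] = metrics
        state["report"] = report
        report.to_frame().to_csv(workdir / "accuracy_report.csv", index=False)
        counters["overall_accuracy"] = metrics["overall_accuracy"]

    state_path.write_bytes(pickle.dumps(state))
    manifest = {
        "stage": name,
        "seed": seed,
        "global_seed": config.seed,
        "config_hash": _config_hash(config),
        "counters": counters,
        "timestamp": time.time(),
    }
    (workdir / f"manifest_{name}.json").write_text(json.dumps(manifest, indent=2))
    return state


def run_all(config: PipelineConfig, workdir: str | Path) -> dict:
    state = {}
    for stage in STAGES:
        state = run_stage(stage, config, workdir)
    return state
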