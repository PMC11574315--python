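"""Simulate the default synthetic scenes and summarise their data density.

Builds the training scene (60x60 px, 6 years) and the held-out
evaluation scene (40x40 px), writes the annual truth maps as GeoTIFFs
and a per-year clear-sky-observation (CSO) summary. The acquisition
model is sparse (~8 clear obs/yr) before 2015 and dense (~30/yr) after,
mirroring the jump in data density when a second satellite family
becomes available.

Run from the repository root: python analysis/01_simulate_scenes.py
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from phenomap.encoding import compute_cso
from phenomap.geoio import LabelRaster, write_label_raster
from phenomap.pipeline import PipelineConfig, run_stage

RESULTS = Path("results")
SCRATCH = Path("scratch/analysis_run")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = PipelineConfig(seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state = run_stage("simulate", cfg, SCRATCH)

    for name in ("train_scene", "eval_scene"):
        scene = state[name]
        outdir = SCRATCH / name
        outdir.mkdir(exist_ok=True)
        for year in scene.truth.years:
            raster = LabelRaster(scene.truth.grid(year).astype(np.uint8),
                                 scene.truth.transform, scene.truth.crs)
            write_label_raster(raster, outdir / f"truth_{year}.tif")
        print(f"{name}: {scene.truth.shape} pixels, years {scene.truth.years}, "
              f"{len(np.unique(scene.truth.data))} distinct codes")

    # CSO: average clear observations per pixel per year, eval scene
    scene = state["eval_scene"]
    rows = []
    for year in scene.truth.years:
        counts = [compute_cso({year: s[year]})[year]
                  for s in scene.series.values()]
        rows.append({"year": year, "mean_cso": np.mean(counts),
                     "min_cso": np.min(counts), "max_cso": np.max(counts)})
    cso = pd.DataFrame(rows)
    cso.to_csv(RESULTS / "cso_by_year.csv", index=False)
    print("\nClear-sky observations per pixel (evaluation scene):")
    print(cso.to_string(index=False))
    print(f"\nTruth maps -> {SCRATCH}/(train|eval)_scene/, "
          f"summary -> {RESULTS}/cso_by_year.csv")


if __name__ == "__main__":
    main()
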