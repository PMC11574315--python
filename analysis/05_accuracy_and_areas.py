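"""Stratified accuracy assessment, peat-exploitation trend and crop areas.

Draws a stratified validation sample from the final-year filtered map,
builds the error matrix and the area-weighted accuracy report (OA/PA/UA
and error-adjusted class areas, all with 95% confidence intervals);
tracks the exploited-peat-bog area through the years; and compares
annual mapped crop areas against an external statistics table (here the
truth areas serve as the stand-in statistics).

Run after 04: python analysis/05_accuracy_and_areas.py
"""

import warnings
from pathlib import Path

import pandas as pd

from phenomap.legend import CROP_GRASS_CODES, DEFAULT_LEGEND
from phenomap.pipeline import PipelineConfig, run_stage
from phenomap.validation import class_area_series, compare_area_series

RESULTS = Path("results")
SCRATCH = Path("scratch/analysis_run")


def area_table(cube, codes):
    rows = []
    for code in codes:
        s = class_area_series(cube, code)
        for year, a in s.items():
            rows.append({"class_code": code, "year": year, "area_km2": a})
    return pd.DataFrame(rows)


def main() -> None:
    cfg = PipelineConfig(seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state = run_stage("validate", cfg, SCRATCH)

    report = state["report"]
    df = report.to_frame()
    df.insert(1, "name", [DEFAULT_LEGEND.name(int(c)) for c in df["class_code"]])
    df.to_csv(RESULTS / "accuracy_report.csv", index=False)
    print(f"Stratified overall accuracy (final year): "
          f"{report.overall_accuracy:.3f} +- {report.overall_accuracy_ci:.3f}")
    print(df.round(3).to_string(index=False))

    cube = state["filtered"]
    truth = state["eval_scene"].truth
    peat = class_area_series(cube, 8).rename("mapped_km2").to_frame()
    peat["truth_km2"] = class_area_series(truth, 8)
    peat.index.name = "year"
    peat.to_csv(RESULTS / "peat_area_series.csv")
    print("\nExploited peat bog area by year (km^2):")
    print(peat.round(4).to_string())

    mapped = area_table(cube, CROP_GRASS_CODES)
    stats = area_table(truth, CROP_GRASS_CODES)
    comp = compare_area_series(mapped, stats)
    comp.to_csv(RESULTS / "crop_area_comparison.csv", index=False)
    mae = comp["relative_error"].abs().mean()
    print(f"\nCrop area vs statistics: mean |relative error| = {mae:.3%}")
    print(f"Tables -> {RESULTS}/accuracy_report.csv, peat_area_series.csv, "
          f"crop_area_comparison.csv")


if __name__ == "__main__":
    main()
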