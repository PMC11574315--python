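"""Mine training pixels with the ten reference-product rules.

Derives synthetic reference products (imperviousness, tree density,
forest type, CLC-like and N2K-like codes) plus index-percentile rasters
from the training scene, evaluates each class rule, samples capped point
sets, and writes the per-rule eligible/sampled counts. Crop training
points come from the truth map of the two most recent years, emulating
parcel labels that exist only for recent seasons.

Run after 01: python analysis/02_mine_training_data.py
"""

import collections
import warnings
from pathlib import Path

import pandas as pd

from phenomap.pipeline import PipelineConfig, run_stage

RESULTS = Path("results")
SCRATCH = Path("scratch/analysis_run")


def main() -> None:
    cfg = PipelineConfig(seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state = run_stage("sample", cfg, SCRATCH)

    l1_counts = collections.Counter(s.label for s in state["l1_samples"])
    wet_counts = collections.Counter(s.label for s in state["wet_samples"])
    crop_counts = collections.Counter(s.label for s in state["crop_samples"])
    rows = (
        [{"set": "level1", "label": k, "n": v} for k, v in sorted(l1_counts.items())]
        + [{"set": "wetland", "label": k, "n": v} for k, v in sorted(wet_counts.items())]
        + [{"set": "crop", "label": k, "n": v} for k, v in sorted(crop_counts.items())]
    )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "training_sample_counts.csv", index=False)
    print("Training samples per model and label:")
    print(df.to_string(index=False))
    print(f"\nCounts -> {RESULTS}/training_sample_counts.csv")


if __name__ == "__main__":
    main()
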