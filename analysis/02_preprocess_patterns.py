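#!/usr/bin/env python
"""Preprocess every run and extract single-trial patterns for both codes.

Per run: nuisance GLM (stimulus + 6 motion + quintic polynomial baseline),
baseline subtraction, temporal z-scoring; then one pattern per trial from the
volume 5-6 s (category code) or 6-7 s (relevance code) after stimulus onset."""

from pathlib import Path

import mvpatms as m
from mvpatms import pipeline as pl, synth

ROOT = Path(__file__).resolve().parent.parent
DATASET = ROOT / "results" / "dataset"
OUT = ROOT / "results" / "patterns"


def main() -> None:
    cfg = m.PipelineConfig.from_file(ROOT / "analysis" / "config.yaml")
    cohort = synth.load_cohort_runs(DATASET)
    patterns = pl.extract_cohort_patterns(cohort, cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    n = 0
    for subject, per_tms in patterns.items():
        for tms, per_code in per_tms.items():
            for code, ps in per_code.items():
                ps.save(OUT / f"{subject}__{tms}__{code}")
                n += 1
    one = patterns[cohort.subjects[0]]["control"]["category"]
    print(f"wrote {n} pattern sets ({one.X.shape[0]} trials x {one.X.shape[1]} voxels each) to {OUT}")


if __name__ == "__main__":
    main()
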