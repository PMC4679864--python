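#!/usr/bin/env python
"""Brain-behavior statistics.

Relates each subject's behavioral accuracy to their decoding accuracies:
Spearman correlation between post-disruption behavioral accuracy and
relevance decoding in the designated region, and a median-split Welch t-test
of the decoding effect (control minus disrupted accuracy) between most- and
least-impaired subjects. Writes results/brain_behavior.json."""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import mvpatms as m
from mvpatms import decode as dec, inference as inf, pipeline as pl, preprocess as pre, synth

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    cfg = m.PipelineConfig.from_file(ROOT / "analysis" / "config.yaml")
    cohort = synth.load_cohort_runs(ROOT / "results" / "dataset")
    behavior = cohort.behavior
    patterns = {}
    for npz in sorted((ROOT / "results" / "patterns").glob("*.npz")):
        subject, tms, code = npz.stem.split("__")
        patterns.setdefault(subject, {}).setdefault(tms, {})[code] = pre.PatternSet.load(
            npz.with_suffix("")
        )

    # observed per-subject decoding accuracies per region and code (no
    # permutations needed for the behavioral statistics)
    subjects = sorted(patterns)
    roi_results = {}
    for code in ("category", "relevance"):
        roi_results[code] = {}
        for roi, mask in cohort.cfg.regions.items():
            obs = {}
            for tms in ("control", "disrupted"):
                accs = []
                for s in subjects:
                    ps = pl.subset_patternset(patterns[s][tms][code], mask)
                    cv = dec.make_run_pair_folds(
                        ps.labels[["run_id", "condition"]].drop_duplicates()
                    )
                    acc, _ = dec.l2_logreg_cv_accuracy(ps, code, cv, cfg.lam)
                    accs.append(acc)
                obs[tms] = accs
            roi_results[code][roi] = {"observed_subjects": obs}

    stats = pl.behavior_analysis(behavior, roi_results, cohort.cfg.behavior.region)
    out = ROOT / "results" / "brain_behavior.json"
    out.write_text(json.dumps(stats, indent=2, sort_keys=True))
    acc = stats["mean_accuracy"]
    print(f"behavioral accuracy: control {acc['control']:.1f}%, disrupted {acc['disrupted']:.1f}%")
    sp = stats.get("spearman_relevance_vs_accuracy", {})
    if "rho" in sp:
        print(
            f"relevance decoding vs post-disruption accuracy: Spearman rho = "
            f"{sp['rho']:.2f}, p = {sp['p']:.3f}"
        )
    for name, ms in stats["median_split"].items():
        if "t" in ms:
            print(
                f"median-split Welch ({name}): t({ms['df']:.2f}) = {ms['t']:.2f}, "
                f"p = {ms['p']:.2f}"
            )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
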