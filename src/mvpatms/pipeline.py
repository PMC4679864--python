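"""End-to-end orchestration: simulate -> preprocess -> decode -> infer.

The pipeline mirrors the study's analysis plan. Per subject and disruption
condition, runs are preprocessed and single-trial patterns extracted at the
code-specific lags; ROI decoding (L2 logistic regression, leave-one-run-pair-
out CV) is tested against matched within-run permutation nulls, above chance
and between conditions; whole-brain GNB searchlight difference maps are
smoothed and entered into bootstrap group inference with empirical cluster
correction; functional ROIs are defined from control-condition searchlight
maps by a group t-test against chance with BH-FDR thresholding; and behavioral
accuracy is related to decoding with a Spearman correlation and a
median-split Welch t-test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import decode as dec
from . import inference as inf
from . import preprocess as pre
from . import synth
from .errors import InvalidArgumentError
from .synth import CONTROL, DISRUPTED, TMS_CONDITIONS, Cohort, SimConfig

SCHEMA_VERSION = 1
CODES = ("category", "relevance")


def regions_from_spec(grid_dims, spec: dict) -> dict[str, np.ndarray]:
    """Build cuboid region masks from {name: {corner: [...], size: [...]}}."""
    regions = {}
    for name, box in spec.items():
        mask = np.zeros(tuple(grid_dims), dtype=bool)
        c = [int(v) for v in box["corner"]]
        s = [int(v) for v in box["size"]]
        mask[c[0] : c[0] + s[0], c[1] : c[1] + s[1], c[2] : c[2] + s[2]] = True
        regions[name] = mask
    return regions


@dataclass
class PipelineConfig:
    """All fixed constants of the analysis, plus the master seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    category_lag_s: tuple[float, float] = (5.0, 6.0)
    relevance_lag_s: tuple[float, float] = (6.0, 7.0)
    lam: float = 1.0
    var_floor: float = 1e-6
    roi_edge: int = 3  # searchlight edge for functional ROI definition
    diff_edge: int = 5  # searchlight edge for the condition-difference analysis
    fwhm_mm: float = 8.0
    n_perm: int = 1000
    n_null: int = 100
    n_boot: int = 100_000
    voxel_alpha: float = 0.005
    cluster_alpha: float = 0.005
    fdr_q: float = 0.0001
    bonferroni: bool = True
    p_rule: str = "greater"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            sim = dict(self.sim)
            if isinstance(sim.get("regions"), dict) and sim["regions"]:
                first = next(iter(sim["regions"].values()))
                if isinstance(first, dict):
                    sim["regions"] = regions_from_spec(sim["grid_dims"], sim["regions"])
            self.sim = SimConfig(**sim)
        for count in (self.n_perm, self.n_null, self.n_boot):
            if count < 1:
                raise InvalidArgumentError("inference counts must be positive")
        for alpha in (self.voxel_alpha, self.cluster_alpha, self.fdr_q):
            if not 0 < alpha < 1:
                raise InvalidArgumentError(f"alpha levels must lie in (0, 1), got {alpha}")
        for window in (self.category_lag_s, self.relevance_lag_s):
            if not window[1] > window[0]:
                raise InvalidArgumentError(f"lag window must be increasing, got {window}")

    def lag_for(self, code: str) -> tuple[float, float]:
        return self.category_lag_s if code == "category" else self.relevance_lag_s

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = synth._config_manifest(self.sim)
        return d


def _seed_int(*key: int) -> int:
    return int(np.random.SeedSequence([int(k) for k in key]).generate_state(1)[0] % 2**31)


# --------------------------------------------------------------------------
# Pattern extraction
# --------------------------------------------------------------------------


def extract_cohort_patterns(
    cohort: Cohort, cfg: PipelineConfig
) -> dict[str, dict[str, dict[str, pre.PatternSet]]]:
    """Full-grid pattern sets: patterns[subject][tms][code]."""
    brain = np.ones(cohort.cfg.grid_dims, dtype=bool)
    out: dict[str, dict[str, dict[str, pre.PatternSet]]] = {}
    for subject in cohort.subjects:
        out[subject] = {}
        for tms in TMS_CONDITIONS:
            runs = cohort.runs[subject][tms]
            cleaned = [
                (pre.preprocess_run(r.volume, r.events, r.motion), r.events) for r in runs
            ]
            out[subject][tms] = {}
            for code in CODES:
                parts = [
                    pre.extract_trial_patterns(vol, ev, cfg.lag_for(code), brain)
                    for vol, ev in cleaned
                ]
                out[subject][tms][code] = pre.PatternSet.concat(parts)
    return out


def subset_patternset(ps: pre.PatternSet, mask: np.ndarray) -> pre.PatternSet:
    """Restrict a full-grid pattern set to the voxels of a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    flat = np.zeros(mask.shape, dtype=bool)
    flat[tuple(ps.voxels.T)] = True
    keep = mask[tuple(ps.voxels.T)]
    return pre.PatternSet(X=ps.X[:, keep], labels=ps.labels.copy(), voxels=ps.voxels[keep])


# --------------------------------------------------------------------------
# ROI analysis
# --------------------------------------------------------------------------


def roi_analysis(
    patterns: dict,
    rois: dict[str, np.ndarray],
    cfg: PipelineConfig,
    codes: tuple[str, ...] = CODES,
) -> dict:
    """Observed ROI decoding, permutation nulls, and the three p-value tiers.

    The same pre-generated per-subject permutation sets (seeded from the
    master seed by subject and code, identically across conditions) are
    reused for every ROI, so condition differences are matched permutation
    by permutation.
    """
    subjects = sorted(patterns.keys())
    results: dict = {code: {} for code in codes}
    family_above = len(rois) * len(TMS_CONDITIONS) * len(codes)
    family_diff = len(rois) * len(codes)

    # permutation sets and CV schemes are ROI independent
    perm_sets: dict = {}
    cv_schemes: dict = {}
    for subject in subjects:
        for tms in TMS_CONDITIONS:
            for code in codes:
                ps = patterns[subject][tms][code]
                run_table = ps.labels[["run_id", "condition"]].drop_duplicates()
                cv_schemes[(subject, tms)] = dec.make_run_pair_folds(run_table)
                seed = _seed_int(cfg.seed, 3, subjects.index(subject), codes.index(code))
                perm_sets[(subject, tms, code)] = inf.generate_label_permutations(
                    ps.label_vector(code), ps.run_ids(), cfg.n_perm, seed
                )

    for code in codes:
        for roi_name, roi_mask in rois.items():
            obs = {tms: np.empty(len(subjects)) for tms in TMS_CONDITIONS}
            nulls = {}
            group_null = {}
            for tms in TMS_CONDITIONS:
                sets, cvs, perms = [], [], []
                for i, subject in enumerate(subjects):
                    roi_ps = subset_patternset(patterns[subject][tms][code], roi_mask)
                    sets.append(roi_ps)
                    cvs.append(cv_schemes[(subject, tms)])
                    perms.append(perm_sets[(subject, tms, code)])
                    acc, _ = dec.l2_logreg_cv_accuracy(roi_ps, code, cvs[-1], cfg.lam)
                    obs[tms][i] = acc
                gnull, snulls = inf.roi_group_null(sets, cvs, perms, code, cfg.lam)
                group_null[tms] = gnull
                nulls[tms] = snulls

            diff = inf.tms_difference_test(
                nulls[CONTROL], nulls[DISRUPTED], obs[CONTROL], obs[DISRUPTED]
            )
            entry = {
                "observed_group": {t: float(obs[t].mean()) for t in TMS_CONDITIONS},
                "observed_subjects": {t: obs[t].tolist() for t in TMS_CONDITIONS},
                "p_above_chance": {},
                "difference": {
                    "observed": diff.observed_difference,
                    "p": diff.p_value,
                    "p_bonferroni": min(1.0, diff.p_value * family_diff)
                    if cfg.bonferroni
                    else None,
                    "family_size": family_diff,
                },
                "subject_nulls": nulls,
            }
            for tms in TMS_CONDITIONS:
                p = inf.empirical_p(group_null[tms], float(obs[tms].mean()), cfg.p_rule)
                entry["p_above_chance"][tms] = {
                    "p": p,
                    "p_bonferroni": min(1.0, p * family_above) if cfg.bonferroni else None,
                    "family_size": family_above,
                }
            results[code][roi_name] = entry
    return results


# --------------------------------------------------------------------------
# Searchlight analyses
# --------------------------------------------------------------------------


def subject_searchlight_map(
    ps: pre.PatternSet,
    labels: np.ndarray,
    grid_dims,
    mask: np.ndarray,
    edge: int,
    code: str,
    var_floor: float = 1e-6,
) -> dec.AccuracyMap:
    run_table = ps.labels[["run_id", "condition"]].drop_duplicates()
    cv = dec.make_run_pair_folds(run_table)
    stack = dec.patternset_to_stack(ps, grid_dims)
    return dec.searchlight_accuracy_map(
        stack, labels, ps.run_ids(), mask, edge, cv, code=code, var_floor=var_floor
    )


def searchlight_difference_analysis(
    patterns: dict,
    cfg: PipelineConfig,
    grid_dims,
    mask: np.ndarray,
    code: str,
) -> dict:
    """Per-subject true and null smoothed difference maps plus group inference."""
    subjects = sorted(patterns.keys())
    vox = cfg.sim.voxel_size_mm
    true_maps, null_maps = [], []
    for si, subject in enumerate(subjects):
        maps_per_cond = {}
        for tms in TMS_CONDITIONS:
            ps = patterns[subject][tms][code]
            seed = _seed_int(cfg.seed, 4, si, CODES.index(code))
            perms = inf.generate_label_permutations(
                ps.label_vector(code), ps.run_ids(), cfg.n_null, seed
            )
            label_matrix = np.vstack([ps.label_vector(code)[None, :], perms.perms])
            run_table = ps.labels[["run_id", "condition"]].drop_duplicates()
            cv = dec.make_run_pair_folds(run_table)
            stack = dec.patternset_to_stack(ps, grid_dims)
            maps = dec.searchlight_accuracy_maps_batch(
                stack, label_matrix, ps.run_ids(), mask, cfg.diff_edge, cv,
                code=code, var_floor=cfg.var_floor,
            )
            maps_per_cond[tms] = [amap.data for amap in maps]
        diffs = [
            inf.smooth_gaussian(c - d, cfg.fwhm_mm, vox)
            for c, d in zip(maps_per_cond[CONTROL], maps_per_cond[DISRUPTED])
        ]
        true_maps.append(diffs[0])
        null_maps.append(np.stack(diffs[1:]))

    rng = np.random.default_rng(_seed_int(cfg.seed, 5, CODES.index(code)))
    sig, report = inf.searchlight_group_difference(
        np.stack(true_maps),
        np.stack(null_maps),
        cfg.n_boot,
        cfg.voxel_alpha,
        cfg.cluster_alpha,
        rng,
    )
    return {
        "true_maps": np.stack(true_maps),
        "significant": sig,
        "report": report,
        "subjects": subjects,
    }


def functional_roi_analysis(
    patterns: dict, cfg: PipelineConfig, grid_dims, mask: np.ndarray, code: str
) -> dict:
    """Control-condition searchlight maps -> smoothed -> group FDR mask."""
    subjects = sorted(patterns.keys())
    maps = []
    for subject in subjects:
        ps = patterns[subject][CONTROL][code]
        amap = subject_searchlight_map(
            ps, ps.label_vector(code), grid_dims, mask, cfg.roi_edge, code, cfg.var_floor
        )
        maps.append(inf.smooth_gaussian(amap.data, cfg.fwhm_mm, cfg.sim.voxel_size_mm))
    roi_mask, mean_map, info = inf.define_functional_rois(np.stack(maps), cfg.fdr_q)
    return {"mask": roi_mask, "mean_map": mean_map, "info": info}


# --------------------------------------------------------------------------
# Behavior
# --------------------------------------------------------------------------


def behavior_analysis(behavior, roi_results: dict, designated_roi: str) -> dict:
    """Brain-behavior statistics on the ROI decoding results."""
    beh = behavior.pivot(index="subject", columns="tms_condition", values="accuracy")
    subjects = sorted(beh.index)
    acc_ctrl = beh.loc[subjects, CONTROL].to_numpy()
    acc_dis = beh.loc[subjects, DISRUPTED].to_numpy()
    decrement = acc_ctrl - acc_dis
    out: dict = {
        "mean_accuracy": {
            CONTROL: float(acc_ctrl.mean() * 100.0),
            DISRUPTED: float(acc_dis.mean() * 100.0),
        },
    }
    rel = roi_results.get("relevance", {}).get(designated_roi)
    if rel is not None and len(subjects) >= 4:
        dec_dis = np.asarray(rel["observed_subjects"][DISRUPTED])
        try:
            rho, p = inf.spearman_corr(acc_dis, dec_dis)
            out["spearman_relevance_vs_accuracy"] = {"rho": rho, "p": p}
        except Exception as exc:  # constant accuracies in tiny smoke runs
            out["spearman_relevance_vs_accuracy"] = {"error": str(exc)}
    out["median_split"] = {}
    for code, rois in roi_results.items():
        for roi_name, entry in rois.items():
            effect = np.asarray(entry["observed_subjects"][CONTROL]) - np.asarray(
                entry["observed_subjects"][DISRUPTED]
            )
            if effect.size >= 4:
                try:
                    t, df, p = inf.median_split_welch(decrement, effect)
                    out["median_split"][f"{code}:{roi_name}"] = {"t": t, "df": df, "p": p}
                except Exception as exc:
                    out["median_split"][f"{code}:{roi_name}"] = {"error": str(exc)}
    return out


# --------------------------------------------------------------------------
# Full experiment
# --------------------------------------------------------------------------


def _clusters_json(report: inf.ClusterReport) -> list[dict]:
    return [
        {
            "size": c.size,
            "center_of_mass": [float(v) for v in c.center_of_mass],
            "survives": bool(c.survives),
        }
        for c in report.clusters
    ]


def analyze_cohort(cohort: Cohort, cfg: PipelineConfig, searchlight: bool = True) -> dict:
    """Run the full analysis on an in-memory cohort; returns the report dict."""
    grid = cohort.cfg.grid_dims
    brain = np.ones(grid, dtype=bool)
    patterns = extract_cohort_patterns(cohort, cfg)
    rois = {name: mask for name, mask in cohort.cfg.regions.items()}

    roi_res = roi_analysis(patterns, rois, cfg)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "roi": {},
        "searchlight": {},
        "functional_rois": {},
    }
    for code in CODES:
        report["roi"][code] = {}
        for roi_name, entry in roi_res[code].items():
            report["roi"][code][roi_name] = {
                k: v for k, v in entry.items() if k != "subject_nulls"
            }

    if searchlight:
        for code in CODES:
            sl = searchlight_difference_analysis(patterns, cfg, grid, brain, code)
            surviving = sl["report"].surviving()
            report["searchlight"][code] = {
                "n_clusters": len(sl["report"].clusters),
                "n_surviving": len(surviving),
                "clusters": _clusters_json(sl["report"]),
                "cluster_size_threshold": sl["report"].cluster_size_threshold,
            }
            if len(cohort.subjects) >= 3:
                froi = functional_roi_analysis(patterns, cfg, grid, brain, code)
                planted = cohort.cfg.regions.get(f"{code}_region")
                overlap = None
                if planted is not None and froi["mask"].any():
                    overlap = float((froi["mask"] & planted).sum() / froi["mask"].sum())
                report["functional_rois"][code] = {
                    "n_voxels": int(froi["mask"].sum()),
                    "fraction_in_planted_region": overlap,
                    **froi["info"],
                }
            else:
                report["functional_rois"][code] = {
                    "skipped": "functional ROI definition needs >= 3 subjects"
                }

    designated = cohort.cfg.behavior.region
    report["behavior"] = behavior_analysis(cohort.behavior, roi_res, designated)
    return report


def run_experiment(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort to disk, analyze it, and write the JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset_dir = out / "dataset"
    synth.simulate_cohort(cfg.sim, dataset_dir)
    # analyze the serialized dataset (not the in-memory cohort) so that the
    # staged CLI path and the end-to-end path produce identical results
    cohort = synth.load_cohort_runs(dataset_dir)
    report = analyze_cohort(cohort, cfg)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
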