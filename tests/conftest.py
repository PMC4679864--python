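"""Shared builders and session-scoped simulation fixtures.

The expensive resampling studies (large batches of simulated null cohorts)
are session fixtures so several tests can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import mvpatms as m
from mvpatms import pipeline as pl, preprocess as pre
from mvpatms.synth import CONTROL, DISRUPTED, TMS_CONDITIONS

CATEGORY_LAG = (5.0, 6.0)
RELEVANCE_LAG = (6.0, 7.0)


def box_regions(grid_dims, **boxes):
    """Cuboid region masks from name=(corner, size) keyword pairs."""
    spec = {name: {"corner": c, "size": s} for name, (c, s) in boxes.items()}
    return pl.regions_from_spec(grid_dims, spec)


def null_sim_config(seed, n_subjects=8, grid=(6, 6, 4), roi_size=(2, 2, 2)):
    """A cohort with no planted codes: pure nuisance + noise."""
    regions = box_regions(grid, roi=((1, 1, 1), roi_size))
    return m.SimConfig(
        n_subjects=n_subjects,
        grid_dims=grid,
        regions=regions,
        category_code={},
        relevance_code={},
        disruption_factors={},
        behavior=m.BehaviorModel(region="roi"),
        seed=seed,
    )


def cohort_code_patterns(cohort, mask, code, lag):
    """patterns[subject][tms][code] restricted to ``mask`` for one code."""
    out = {}
    for subject in cohort.subjects:
        out[subject] = {}
        for tms in TMS_CONDITIONS:
            ps = pre.patterns_from_runs(cohort.runs[subject][tms], lag, mask)
            out[subject][tms] = {code: ps}
    return out


def null_roi_cohort_stats(seed, n_perm=99):
    """Above-chance and condition-difference tests on one null cohort."""
    cfg = null_sim_config(seed)
    pcfg = m.PipelineConfig(sim=cfg, n_perm=n_perm, seed=seed)
    cohort = m.simulate_cohort_arrays(cfg)
    mask = cfg.regions["roi"]
    pats = cohort_code_patterns(cohort, mask, "category", CATEGORY_LAG)
    res = pl.roi_analysis(pats, {"roi": mask}, pcfg, codes=("category",))
    entry = res["category"]["roi"]
    return {
        "p_control": entry["p_above_chance"][CONTROL]["p"],
        "p_disrupted": entry["p_above_chance"][DISRUPTED]["p"],
        "p_diff": entry["difference"]["p"],
        "obs_control": entry["observed_subjects"][CONTROL],
        "obs_disrupted": entry["observed_subjects"][DISRUPTED],
    }


@pytest.fixture(scope="session")
def null_roi_cohorts():
    """200 independent fully null cohorts, 8 subjects, 99 permutations each."""
    return [null_roi_cohort_stats(seed) for seed in range(200)]


def null_searchlight_cohort_surviving(seed, n_null=20, n_boot=2000, grid=(12, 12, 8)):
    """Whole-brain difference inference on one null cohort; True if any
    cluster survives the empirical cluster correction."""
    regions = box_regions(grid, roi=((4, 4, 2), (3, 3, 3)))
    cfg = m.SimConfig(
        n_subjects=8,
        grid_dims=grid,
        regions=regions,
        category_code={},
        relevance_code={},
        disruption_factors={},
        behavior=m.BehaviorModel(region="roi"),
        seed=seed,
    )
    pcfg = m.PipelineConfig(sim=cfg, n_null=n_null, n_boot=n_boot, seed=seed)
    cohort = m.simulate_cohort_arrays(cfg)
    brain = np.ones(grid, dtype=bool)
    pats = cohort_code_patterns(cohort, brain, "category", CATEGORY_LAG)
    sl = pl.searchlight_difference_analysis(pats, pcfg, grid, brain, "category")
    return len(sl["report"].surviving()) > 0


@pytest.fixture(scope="session")
def null_searchlight_cohorts():
    """50 null cohorts through the scaled-down cluster-corrected pipeline."""
    return [null_searchlight_cohort_surviving(seed) for seed in range(300, 350)]


def planted_relevance_config(seed, attenuation, n_subjects=8, grid=(6, 6, 4), amp=0.2):
    """Relevance code planted in one 27-voxel region, attenuated when disrupted."""
    regions = box_regions(grid, roi=((1, 1, 1), (3, 3, 3)))
    return m.SimConfig(
        n_subjects=n_subjects,
        grid_dims=grid,
        regions=regions,
        category_code={},
        relevance_code={"roi": amp},
        disruption_factors={"roi": attenuation},
        behavior=m.BehaviorModel(region="roi"),
        seed=seed,
    )


def difference_test_p(seed, attenuation, n_subjects=8, n_perm=200, amp=0.2):
    """p-value of the matched-permutation condition-difference test."""
    cfg = planted_relevance_config(seed, attenuation, n_subjects=n_subjects, amp=amp)
    pcfg = m.PipelineConfig(sim=cfg, n_perm=n_perm, seed=seed)
    cohort = m.simulate_cohort_arrays(cfg)
    mask = cfg.regions["roi"]
    pats = cohort_code_patterns(cohort, mask, "relevance", RELEVANCE_LAG)
    res = pl.roi_analysis(pats, {"roi": mask}, pcfg, codes=("relevance",))
    return res["relevance"]["roi"]["difference"]["p"]


@pytest.fixture
def tiny_pipeline_config():
    regions = {
        "category_region": {"corner": [1, 1, 1], "size": [3, 3, 3]},
        "relevance_region": {"corner": [6, 6, 4], "size": [3, 3, 3]},
    }
    return m.PipelineConfig(
        sim=dict(n_subjects=3, grid_dims=[10, 10, 8], regions=regions, seed=11),
        n_perm=19,
        n_null=3,
        n_boot=200,
        seed=11,
    )
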