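"""Inference tests: permutations, empirical p, difference test, smoothing,
FDR ROI definition, clusters, bootstrap group inference, behavioral stats."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mvpatms import inference as inf
from mvpatms.errors import (
    AlignmentError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)


class TestPermutations:
    def test_within_run_counts_preserved(self):
        labels = np.array(["face", "scene"] * 20, dtype=object)
        run_ids = np.repeat([f"r{i}" for i in range(4)], 10)
        ps = inf.generate_label_permutations(labels, run_ids, 50, seed=0)
        assert ps.perms.shape == (50, 40)
        for perm in ps.perms:
            for r in np.unique(run_ids):
                sel = run_ids == r
                assert (perm[sel] == "face").sum() == 5  # 5/5 per run preserved
            assert not np.array_equal(perm, labels)  # identity excluded

    def test_two_trial_run_is_exhaustive(self):
        labels = np.array(["A", "B"], dtype=object)
        run_ids = np.array(["r0", "r0"])
        ps = inf.generate_label_permutations(labels, run_ids, 30, seed=1)
        variants = {tuple(p) for p in ps.perms}
        assert variants <= {("A", "B"), ("B", "A")}

    def test_determinism(self):
        labels = np.array(["A", "B"] * 10, dtype=object)
        run_ids = np.repeat(["r0", "r1"], 10)
        a = inf.generate_label_permutations(labels, run_ids, 20, seed=7)
        b = inf.generate_label_permutations(labels, run_ids, 20, seed=7)
        assert np.array_equal(a.perms, b.perms)
        assert a.set_id == b.set_id


class TestEmpiricalP:
    def test_direct_count(self):
        assert inf.empirical_p(np.array([0.4, 0.5, 0.6, 0.7]), 0.65) == 0.25

    def test_boundaries(self):
        null = np.array([0.4, 0.5, 0.6])
        assert inf.empirical_p(null, 0.99) == 0.0
        assert inf.empirical_p(null, 0.1) == 1.0

    def test_add_one_variant_never_zero(self):
        null = np.array([0.4, 0.5, 0.6])
        assert inf.empirical_p(null, 0.99, rule="add_one") == pytest.approx(1 / 4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10**6), st.floats(-2, 2))
    def test_bounds_property(self, seed, observed):
        null = np.random.default_rng(seed).normal(size=17)
        p = inf.empirical_p(null, observed)
        assert 0.0 <= p <= 1.0
        assert p == (null > observed).mean()

    def test_empty_null_rejected(self):
        with pytest.raises(InvalidArgumentError):
            inf.empirical_p(np.array([]), 0.5)


class TestDifferenceTest:
    def test_symmetric_null_gives_half(self):
        rng = np.random.default_rng(0)
        nulls = rng.normal(0.5, 0.02, size=(4, 201))
        obs = np.full(4, 0.5)
        res = inf.tms_difference_test(nulls, nulls, obs, obs)
        assert res.observed_difference == 0.0
        # identical nulls cancel exactly -> null differences all zero, and no
        # zero exceeds the observed zero
        assert res.p_value == 0.0

    def test_independent_null_centered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.5, 0.02, size=(6, 400))
        b = rng.normal(0.5, 0.02, size=(6, 400))
        res = inf.tms_difference_test(a, b, np.full(6, 0.5), np.full(6, 0.5))
        assert 0.35 < res.p_value < 0.65

    def test_single_subject_count_example(self):
        res = inf.tms_difference_test(
            np.array([[0.0, 0.1]]), np.array([[0.0, 0.0]]), [0.2], [0.0]
        )
        assert res.observed_difference == pytest.approx(0.2)
        assert res.p_value == 0.0

    def test_unmatched_counts_rejected(self):
        with pytest.raises(AlignmentError):
            inf.tms_difference_test(
                np.zeros((2, 10)), np.zeros((2, 11)), np.zeros(2), np.zeros(2)
            )


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 6, 4))
        assert np.array_equal(inf.smooth_gaussian(x, 0.0, 3.5), x)

    def test_constant_map_unchanged(self):
        x = np.full((8, 8, 6), 0.7)
        out = inf.smooth_gaussian(x, 8.0, 3.5)
        assert np.allclose(out, 0.7)

    def test_delta_peaks_at_source_and_decays(self):
        x = np.zeros((9, 9, 9))
        x[4, 4, 4] = 1.0
        out = inf.smooth_gaussian(x, 8.0, 3.5)
        assert out.argmax() == np.ravel_multi_index((4, 4, 4), x.shape)
        assert out[4, 4, 4] > out[4, 4, 6] > out[4, 4, 8]

    def test_nan_voxels_stay_nan_and_do_not_leak(self):
        x = np.full((6, 6, 4), 1.0)
        x[2, 2, 2] = np.nan
        out = inf.smooth_gaussian(x, 8.0, 3.5)
        assert np.isnan(out[2, 2, 2])
        finite = out[np.isfinite(out)]
        assert np.allclose(finite, 1.0)  # masked normalization preserves level

    def test_negative_fwhm_rejected(self):
        with pytest.raises(InvalidArgumentError):
            inf.smooth_gaussian(np.zeros((3, 3, 3)), -1.0, 3.5)


class TestFunctionalRois:
    def test_all_chance_maps_give_empty_mask(self):
        maps = np.full((5, 6, 6, 4), 0.5)
        with pytest.warns(UserWarning):
            mask, mean_map, info = inf.define_functional_rois(maps, q=0.0001)
        assert not mask.any()
        assert np.isnan(mean_map).all()

    def test_strong_region_detected(self):
        rng = np.random.default_rng(0)
        maps = rng.normal(0.5, 0.01, size=(12, 6, 6, 4))
        maps[:, 1:3, 1:3, 1:3] += 0.2
        mask, mean_map, _ = inf.define_functional_rois(maps, q=0.0001)
        assert mask[1:3, 1:3, 1:3].all()
        assert mean_map[1, 1, 1] > 0.65

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InvalidArgumentError):
            inf.define_functional_rois(np.full((2, 3, 3, 3), 0.6))


def bfs_clusters(binary):
    """Brute-force 6-connectivity components by breadth-first search."""
    binary = np.asarray(binary, bool)
    seen = np.zeros_like(binary)
    sizes = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        queue, size = [start], 0
        seen[start] = True
        while queue:
            v = queue.pop()
            size += 1
            for axis in range(3):
                for d in (-1, 1):
                    w = list(v)
                    w[axis] += d
                    w = tuple(w)
                    if all(0 <= w[i] < binary.shape[i] for i in range(3)):
                        if binary[w] and not seen[w]:
                            seen[w] = True
                            queue.append(w)
        sizes.append(size)
    return sorted(sizes, reverse=True)


class TestClusters:
    def test_edge_sharing_voxels_are_separate_clusters(self):
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = m[1, 1, 0] = True  # share an edge, not a face
        assert len(inf.extract_clusters(m).clusters) == 2

    def test_solid_block_single_cluster(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        report = inf.extract_clusters(m)
        assert [c.size for c in report.clusters] == [27]
        assert report.clusters[0].center_of_mass == (2.0, 2.0, 2.0)

    def test_empty_map_empty_report(self):
        assert inf.extract_clusters(np.zeros((4, 4, 4), bool)).clusters == []

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_sizes_match_bfs_oracle(self, seed):
        binary = np.random.default_rng(seed).random((6, 6, 5)) > 0.6
        report = inf.extract_clusters(binary)
        assert sorted((c.size for c in report.clusters), reverse=True) == bfs_clusters(
            binary
        )


class TestGroupDifferenceMaps:
    def test_all_zero_maps_give_no_voxels(self):
        true = np.zeros((4, 6, 6, 4))
        null = np.zeros((4, 10, 6, 6, 4))
        with pytest.warns(UserWarning):  # small n_boot warning
            sig, report = inf.searchlight_group_difference(true, null, 50, rng=0)
        assert not sig.any()
        assert report.surviving() == []

    def test_bootstrap_bit_reproducible(self):
        rng = np.random.default_rng(3)
        true = rng.normal(0, 0.01, size=(5, 8, 8, 6))
        true[:, 2:5, 2:5, 2:4] += 0.15
        null = rng.normal(0, 0.01, size=(5, 15, 8, 8, 6))
        out1 = inf.searchlight_group_difference(true, null, 400, rng=42)
        out2 = inf.searchlight_group_difference(true, null, 400, rng=42)
        assert np.array_equal(out1[0], out2[0])
        assert [c.size for c in out1[1].clusters] == [c.size for c in out2[1].clusters]
        assert out1[1].cluster_size_threshold == out2[1].cluster_size_threshold

    def test_planted_difference_recovered(self):
        rng = np.random.default_rng(5)
        true = rng.normal(0, 0.01, size=(6, 8, 8, 6))
        true[:, 2:5, 2:5, 2:4] += 0.2
        null = rng.normal(0, 0.01, size=(6, 20, 8, 8, 6))
        sig, report = inf.searchlight_group_difference(true, null, 1000, rng=1)
        assert len(report.surviving()) == 1
        planted = np.zeros((8, 8, 6), bool)
        planted[2:5, 2:5, 2:4] = True
        assert sig[planted].mean() > 0.9
        assert sig[~planted].mean() < 0.05


class TestSpearman:
    def test_monotone_map_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = inf.spearman_corr(x, x**2)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = inf.spearman_corr(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_exhaustive_enumeration(self):
        x = np.array([0.3, 1.2, -0.5, 2.2, 0.9])
        y = np.array([1.0, 0.1, 0.4, 2.0, 1.4])
        rho, p = inf.spearman_corr(x, y)
        # independent oracle: classic 1 - 6*sum(d^2)/(n(n^2-1)) over all 120
        # rank assignments (no ties here)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        n = 5
        rho_oracle = 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))
        assert rho == pytest.approx(rho_oracle, abs=1e-12)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = 1 - 6 * np.sum((rx - np.array(perm)) ** 2) / (n * (n**2 - 1))
            total += 1
            if abs(r) >= abs(rho_oracle) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = inf.spearman_corr(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, abs=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            inf.spearman_corr(np.ones(5), np.arange(5.0))


class TestMedianSplitWelch:
    def test_matches_closed_form_and_scipy(self):
        decrements = np.array([0.01, 0.05, 0.02, 0.08, 0.03, 0.07, 0.00, 0.06])
        effects = np.array([0.02, 0.09, 0.01, 0.12, 0.03, 0.08, 0.00, 0.11])
        t, df, p = inf.median_split_welch(decrements, effects)
        order = np.argsort(decrements, kind="stable")
        most, least = effects[order[4:]], effects[order[:4]]
        ref = stats.ttest_ind(most, least, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        va, vb = most.var(ddof=1) / 4, least.var(ddof=1) / 4
        df_oracle = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        assert df == pytest.approx(df_oracle, abs=1e-12)

    def test_identical_groups_near_zero_t(self):
        decrements = np.arange(8.0)
        effects = np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5001])
        t, df, p = inf.median_split_welch(decrements, effects)
        assert abs(t) < 3  # no systematic group difference

    def test_separated_groups_significant(self):
        decrements = np.array([0.0, 0.01, 0.02, 0.1, 0.11, 0.12])
        effects = np.array([0.001, -0.001, 0.0005, 1.0, 0.999, 1.001])
        t, df, p = inf.median_split_welch(decrements, effects)
        assert t > 0
        assert p < 0.01

    def test_odd_n_excludes_median_subject(self):
        decrements = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        effects = np.array([0.0, 0.01, 99.0, 1.0, 1.01])
        t, df, p = inf.median_split_welch(decrements, effects)
        # the median subject's extreme effect is excluded entirely
        assert np.isfinite(t) and t > 0


class TestNullCalibration:
    """Properties of the permutation machinery on fully null cohorts.

    These share the session-scoped batch of simulated null cohorts with the
    acceptance suite.
    """

    def test_difference_p_uniform_over_null_cohorts(self, null_roi_cohorts):
        pvals = np.array([c["p_diff"] for c in null_roi_cohorts])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_null_decoding_centered_on_chance(self, null_roi_cohorts):
        accs = np.concatenate([c["obs_control"] for c in null_roi_cohorts])
        n_trials = 200  # test predictions per subject (10 runs x 20 trials)
        sem = 0.5 / np.sqrt(n_trials * accs.size)
        assert abs(accs.mean() - 0.5) < 4 * sem + 0.005
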