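"""Classifier tests: CV folds, logistic regression, GNB, searchlight."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mvpatms import decode as dec
from mvpatms.errors import InvalidFoldError, PairingError
from mvpatms.preprocess import PatternSet


def run_table(n_pairs):
    return pd.DataFrame(
        {
            "run_id": [f"run-{i:02d}" for i in range(2 * n_pairs)],
            "condition": ["remember_faces"] * n_pairs + ["remember_scenes"] * n_pairs,
        }
    )


class TestFolds:
    def test_five_pairs_give_five_folds(self):
        cv = dec.make_run_pair_folds(run_table(5))
        assert cv.n_folds == 5
        test_runs = [r for _, test in cv.folds for r in test]
        assert sorted(test_runs) == sorted(run_table(5)["run_id"])  # partition
        for train, test in cv.folds:
            assert len(test) == 2 and len(train) == 8
            assert not set(train) & set(test)

    def test_single_pair_rejected(self):
        with pytest.raises(PairingError):
            dec.make_run_pair_folds(run_table(1))

    def test_unequal_counts_rejected(self):
        t = run_table(3).iloc[:-1]
        with pytest.raises(PairingError):
            dec.make_run_pair_folds(t)


def toy_patterns(n_per_run=10, n_runs=4, n_vox=2, sep=3.0, noise=0.3, seed=0):
    """Linearly separable face/scene patterns spread over paired runs."""
    rng = np.random.default_rng(seed)
    rows, cats, runs, conds = [], [], [], []
    for r in range(n_runs):
        cond = "remember_faces" if r < n_runs // 2 else "remember_scenes"
        for i in range(n_per_run):
            cat = "face" if i % 2 == 0 else "scene"
            mu = sep / 2 if cat == "face" else -sep / 2
            rows.append(rng.normal(mu, noise, n_vox))
            cats.append(cat)
            runs.append(f"run-{r:02d}")
            conds.append(cond)
    labels = pd.DataFrame(
        {
            "category": cats,
            "relevance": np.where(
                (np.array(cats) == "face") == (np.array(conds) == "remember_faces"),
                "relevant",
                "irrelevant",
            ),
            "run_id": runs,
            "condition": conds,
            "tms_condition": "control",
        }
    )
    return PatternSet(X=np.array(rows), labels=labels, voxels=np.zeros((n_vox, 3), int))


class TestLogReg:
    def test_separable_patterns_decoded_perfectly(self):
        ps = toy_patterns()
        cv = dec.make_run_pair_folds(ps.labels[["run_id", "condition"]].drop_duplicates())
        acc, per_fold = dec.l2_logreg_cv_accuracy(ps, "category", cv, lam=0.01)
        assert acc == 1.0
        assert acc == pytest.approx(np.mean(per_fold))

    def test_matches_sklearn_reference(self):
        # independent cross-check: scikit-learn's L2 logistic regression with
        # unpenalized intercept minimizes the same objective
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 5))
        y = (rng.random(80) < 0.5).astype(float)
        lam = 2.0
        w = dec.fit_l2_logreg(X, y, lam=lam)
        ref = LogisticRegression(C=1.0 / lam, tol=1e-10, max_iter=5000)
        ref.fit(X, y)
        assert np.allclose(w[0], ref.intercept_[0], atol=1e-5)
        assert np.allclose(w[1:], ref.coef_[0], atol=1e-5)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(7)
        ps = toy_patterns(n_per_run=50, sep=3.0)
        perm = ps.labels.copy()
        for run in perm["run_id"].unique():  # shuffle independently of patterns
            idx = perm.index[perm["run_id"] == run]
            perm.loc[idx, "category"] = rng.permutation(
                perm.loc[idx, "category"].to_numpy()
            )
        shuffled = PatternSet(X=ps.X, labels=perm, voxels=ps.voxels)
        cv = dec.make_run_pair_folds(ps.labels[["run_id", "condition"]].drop_duplicates())
        acc, _ = dec.l2_logreg_cv_accuracy(shuffled, "category", cv)
        assert 0.35 <= acc <= 0.65

    def test_infinite_penalty_shrinks_weights_to_tie_rule(self):
        # as lam grows the weights vanish (~ grad/lam); with zero weights the
        # 0.5-probability tie goes to the smaller class, i.e. chance on a
        # balanced test set
        ps = toy_patterns()
        y = (ps.label_vector("category") == "scene").astype(float)
        w_big = dec.fit_l2_logreg(ps.X, y, lam=1e8)
        w_huge = dec.fit_l2_logreg(ps.X, y, lam=1e10)
        assert np.linalg.norm(w_big[1:]) < 1e-6
        assert np.linalg.norm(w_huge[1:]) < np.linalg.norm(w_big[1:]) / 10
        assert abs(w_huge[0]) < 1e-8  # balanced classes: intercept at 0
        z = np.zeros(ps.X.shape[0])  # exact zero-weight limit
        pred = np.where(z > 0, "scene", "face")
        assert (pred == ps.label_vector("category")).mean() == pytest.approx(0.5)

    def test_single_class_training_fold_rejected(self):
        ps = toy_patterns()
        bad = ps.labels.copy()
        bad["category"] = np.where(bad["run_id"] == "run-00", "face", bad["category"])
        bad.loc[bad["run_id"] != "run-00", "category"] = "face"
        bad.loc[bad.index[:1], "category"] = "scene"  # only one scene trial overall
        broken = PatternSet(X=ps.X, labels=bad, voxels=ps.voxels)
        cv = dec.make_run_pair_folds(ps.labels[["run_id", "condition"]].drop_duplicates())
        with pytest.raises(InvalidFoldError):
            dec.l2_logreg_cv_accuracy(broken, "category", cv)


def brute_force_gnb(train_X, train_y, test_X):
    """Direct density evaluation with pooled within-class variance."""
    classes = sorted(set(train_y))
    n = len(train_y)
    means, priors = {}, {}
    ssw = np.zeros(train_X.shape[1])
    for c in classes:
        Xc = train_X[np.asarray(train_y) == c]
        means[c] = Xc.mean(axis=0)
        priors[c] = len(Xc) / n
        ssw += ((Xc - means[c]) ** 2).sum(axis=0)
    var = np.maximum(ssw / (n - len(classes)), 1e-6)
    preds = []
    for x in test_X:
        best, best_score = None, -np.inf
        for c in classes:
            dens = stats.norm.pdf(x, loc=means[c], scale=np.sqrt(var))
            score = np.sum(np.log(dens)) + np.log(priors[c])
            if score > best_score:  # strict: ties keep the smaller label
                best, best_score = c, score
        preds.append(best)
    return np.array(preds, dtype=object)


class TestGNB:
    def test_matches_bruteforce_density_oracle(self):
        rng = np.random.default_rng(3)
        Xtr = rng.normal(size=(40, 3))
        ytr = np.array(["a", "b"] * 20, dtype=object)
        Xte = rng.normal(size=(25, 3))
        assert np.array_equal(
            dec.gnb_fit_predict(Xtr, ytr, Xte), brute_force_gnb(Xtr, ytr, Xte)
        )

    def test_separated_classes_perfect(self):
        rng = np.random.default_rng(0)
        Xtr = np.vstack([rng.normal(-5, 0.1, (10, 4)), rng.normal(5, 0.1, (10, 4))])
        ytr = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        Xte = np.vstack([rng.normal(-5, 0.1, (5, 4)), rng.normal(5, 0.1, (5, 4))])
        assert np.array_equal(
            dec.gnb_fit_predict(Xtr, ytr, Xte), np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        )

    def test_exact_tie_returns_smaller_label(self):
        Xtr = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        ytr = np.array(["a", "a", "b", "b"], dtype=object)
        pred = dec.gnb_fit_predict(Xtr, ytr, np.array([[0.0]]))
        assert pred[0] == "a"


def grid_patterns(n_per_run=10, n_runs=4, grid=(4, 4, 3), seed=0, signal_vox=None, amp=0.0):
    rng = np.random.default_rng(seed)
    n = n_per_run * n_runs
    stack = rng.normal(size=(n,) + grid)
    cats = np.array(["face", "scene"] * (n // 2), dtype=object)
    runs = np.repeat([f"run-{r:02d}" for r in range(n_runs)], n_per_run)
    conds = np.repeat(["remember_faces", "remember_scenes"], n // 2)
    if signal_vox is not None:
        signs = np.where(cats == "face", 1.0, -1.0)
        for v in signal_vox:
            stack[(slice(None),) + v] += amp * signs
    table = pd.DataFrame({"run_id": runs, "condition": conds})
    cv = dec.make_run_pair_folds(table.drop_duplicates())
    return stack, cats, runs, cv


class TestSearchlight:
    def test_two_center_toy_mask_matches_per_center_oracle(self):
        stack, cats, runs, cv = grid_patterns()
        mask = np.zeros((4, 4, 3), bool)
        centers = [(1, 2, 1), (2, 2, 1)]  # >= half cube occupancy under the mask
        mask[1:4, 1:4, :] = True  # give the centers some neighbours
        amap = dec.searchlight_accuracy_map(stack, cats, runs, mask, 3, cv)
        for center in centers:
            # oracle: gather the cube's in-mask voxels and run plain GNB per fold
            sl = tuple(
                slice(max(0, c - 1), min(d, c + 2)) for c, d in zip(center, (4, 4, 3))
            )
            cube = np.zeros((4, 4, 3), bool)
            cube[sl] = True
            cube &= mask
            feats = stack[:, cube]
            fold_accs = []
            for train, test in cv.folds:
                tr = np.isin(runs, train)
                te = np.isin(runs, test)
                pred = dec.gnb_fit_predict(feats[tr], cats[tr], feats[te])
                fold_accs.append((pred == cats[te]).mean())
            assert amap.data[center] == pytest.approx(np.mean(fold_accs), abs=1e-10)

    def test_edge_one_equals_single_voxel_gnb(self):
        stack, cats, runs, cv = grid_patterns(seed=5)
        mask = np.ones((4, 4, 3), bool)
        amap = dec.searchlight_accuracy_map(stack, cats, runs, mask, 1, cv)
        v = (2, 1, 0)
        feats = stack[:, v[0], v[1], v[2]][:, None]
        fold_accs = []
        for train, test in cv.folds:
            tr = np.isin(runs, train)
            te = np.isin(runs, test)
            pred = dec.gnb_fit_predict(feats[tr], cats[tr], feats[te])
            fold_accs.append((pred == cats[te]).mean())
        assert amap.data[v] == pytest.approx(np.mean(fold_accs), abs=1e-10)

    def test_batch_maps_equal_looped_single_maps(self):
        stack, cats, runs, cv = grid_patterns(seed=2)
        rng = np.random.default_rng(0)
        mask = rng.random((4, 4, 3)) > 0.2
        L = np.stack([cats] + [rng.permutation(cats) for _ in range(3)])
        batch = dec.searchlight_accuracy_maps_batch(stack, L, runs, mask, 3, cv)
        for b in range(L.shape[0]):
            single = dec.searchlight_accuracy_map(stack, L[b], runs, mask, 3, cv)
            assert np.array_equal(np.isnan(single.data), np.isnan(batch[b].data))
            assert np.nanmax(np.abs(single.data - batch[b].data)) < 1e-10

    def test_planted_signal_raises_map_contrast(self):
        signal_vox = [(1, 1, 1), (1, 2, 1), (2, 1, 1), (2, 2, 1)]
        stack, cats, runs, cv = grid_patterns(
            n_per_run=20, seed=8, signal_vox=signal_vox, amp=1.0
        )
        mask = np.ones((4, 4, 3), bool)
        amap = dec.searchlight_accuracy_map(stack, cats, runs, mask, 3, cv)
        planted = np.zeros((4, 4, 3), bool)
        for v in signal_vox:
            planted[v] = True
        inside = np.nanmean(amap.data[planted & amap.valid])
        outside = np.nanmean(amap.data[~planted & amap.valid])
        assert inside > outside

    def test_map_invariants(self):
        stack, cats, runs, cv = grid_patterns(seed=9)
        mask = np.ones((4, 4, 3), bool)
        amap = dec.searchlight_accuracy_map(stack, cats, runs, mask, 3, cv)
        vals = amap.data[amap.valid]
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(np.isnan(amap.data[~amap.valid]))
        # an interior 3-cube in a full mask holds all 27 candidate voxels
        assert amap.valid[1, 1, 1]
        # corner centers keep only 8 of 27 voxels -> below half occupancy
        assert not amap.valid[0, 0, 0]
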