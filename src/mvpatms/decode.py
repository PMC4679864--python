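"""Classifiers and cross-validation.

ROI decoding uses a binary L2-regularized logistic regression (Newton
iterations, penalty on weights but not the intercept); whole-volume decoding
uses a Gaussian Naive Bayes cubic searchlight. Both run under a
leave-one-run-pair-out cross-validation scheme in which each fold holds out
one "Remember Faces" and one "Remember Scenes" run as the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .errors import (
    ConvergenceError,
    InvalidArgumentError,
    InvalidFoldError,
    PairingError,
    ShapeError,
)
from .preprocess import PatternSet

VAR_FLOOR = 1e-6


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------


@dataclass
class CVScheme:
    """Ordered folds of (train run ids, test run ids = one run per task)."""

    folds: list[tuple[tuple[str, ...], tuple[str, ...]]]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_run_pair_folds(
    run_table: pd.DataFrame,
    rng: np.random.Generator | None = None,
    random_pairing: bool = False,
) -> CVScheme:
    """Pair runs across the two task conditions and leave one pair out.

    ``run_table`` needs columns ``run_id`` and ``condition``. Pairing is by
    sorted run order unless ``random_pairing`` requests a seeded shuffle.
    """
    conditions = sorted(run_table["condition"].unique())
    if len(conditions) != 2:
        raise PairingError(f"expected exactly 2 task conditions, got {conditions}")
    groups = {
        c: sorted(run_table.loc[run_table["condition"] == c, "run_id"].unique())
        for c in conditions
    }
    a, b = (groups[c] for c in conditions)
    if len(a) != len(b):
        raise PairingError(f"unequal run counts per condition: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise PairingError("need at least 2 run pairs; 1 pair leaves an empty training set")
    if random_pairing:
        if rng is None:
            raise InvalidArgumentError("random pairing requires an rng")
        a = list(rng.permutation(a))
        b = list(rng.permutation(b))
    all_runs = set(a) | set(b)
    folds = []
    for ra, rb in zip(a, b):
        test = (ra, rb)
        train = tuple(sorted(all_runs - set(test)))
        folds.append((train, test))
    return CVScheme(folds=folds)


# --------------------------------------------------------------------------
# L2 logistic regression (Newton), single and batched over label vectors
# --------------------------------------------------------------------------


def _fit_logreg_newton_batch(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Fit B ridge-logistic models sharing a design X against B label vectors.

    X is (n, d) without intercept column; Y is (B, n) in {0, 1}. The L2
    penalty ``lam`` applies to the weights only, never the intercept.
    Returns coefficients (B, d + 1), intercept first.
    """
    n, d = X.shape
    Xa = np.column_stack([np.ones(n), X])
    B = Y.shape[0]
    pen = np.full(d + 1, lam)
    pen[0] = 0.0
    W = np.zeros((B, d + 1))
    for _ in range(max_iter):
        z = W @ Xa.T  # (B, n)
        p = expit(z)
        grad = (p - Y) @ Xa + W * pen  # (B, d+1)
        gnorm = np.linalg.norm(grad, axis=1)
        if np.all(gnorm < tol):
            return W
        s = p * (1.0 - p)  # (B, n)
        H = np.matmul((s[:, :, None] * Xa[None, :, :]).transpose(0, 2, 1), Xa)
        H += np.diag(pen)[None, :, :]
        # tiny Tikhonov term keeps the solve well posed when p saturates
        H += 1e-10 * np.eye(d + 1)[None, :, :]
        W = W - np.linalg.solve(H, grad[:, :, None])[:, :, 0]
    z = W @ Xa.T
    p = expit(z)
    grad = (p - Y) @ Xa + W * pen
    gnorm = np.linalg.norm(grad, axis=1)
    if np.any(gnorm >= tol):
        worst = float(gnorm.max())
        raise ConvergenceError(
            f"logistic regression did not converge in {max_iter} Newton steps "
            f"(max |grad| = {worst:.3e}, lam = {lam}, n = {n}, d = {d})"
        )
    return W


def fit_l2_logreg(
    X: np.ndarray, y: np.ndarray, lam: float = 1.0, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Single-model convenience wrapper; y in {0, 1}; returns (d + 1,)."""
    return _fit_logreg_newton_batch(X, np.asarray(y, float)[None, :], lam, tol, max_iter)[0]


def _binary_classes(labels: np.ndarray) -> tuple:
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 2:
        raise InvalidFoldError(f"binary classification requires 2 classes, got {classes}")
    return tuple(classes)


def l2_logreg_cv_accuracy(
    patterns: PatternSet,
    code: str,
    cv: CVScheme,
    lam: float = 1.0,
) -> tuple[float, list[float]]:
    """Cross-validated ROI decoding accuracy for one code.

    Predictions threshold the fitted class-1 probability at 0.5; an exact
    tie goes to the lexicographically smaller class. Returns the unweighted
    mean over folds and the per-fold accuracies.
    """
    labels = patterns.label_vector(code)
    accs = cv_accuracy_batch(patterns.X, labels[None, :], patterns.run_ids(), cv, lam,
                             true_labels=labels, per_fold=True)
    mean_acc, per_fold = accs
    return float(mean_acc[0]), [float(a) for a in per_fold[0]]


def cv_accuracy_batch(
    X: np.ndarray,
    label_matrix: np.ndarray,
    run_ids: np.ndarray,
    cv: CVScheme,
    lam: float = 1.0,
    true_labels: np.ndarray | None = None,
    per_fold: bool = False,
):
    """Leave-one-run-pair-out accuracy for B label vectors sharing one X.

    Training *and* test labels come from each row of ``label_matrix``
    (permuted labels follow the cross-validation structure of the original
    analysis), unless ``true_labels`` is given, in which case test accuracy
    is always scored against it (used for the observed statistic; for
    permutations the permuted labels are the ground truth of their own null
    world, so both conventions coincide in distribution).
    """
    label_matrix = np.asarray(label_matrix)
    B, n = label_matrix.shape
    if X.shape[0] != n or run_ids.shape[0] != n:
        raise ShapeError("label matrix, patterns and run ids must align")
    classes = _binary_classes(label_matrix[0])
    Y = (label_matrix == classes[1]).astype(float)
    score_against = Y if true_labels is None else np.broadcast_to(
        (np.asarray(true_labels) == classes[1]).astype(float), Y.shape
    )

    fold_accs = np.empty((B, cv.n_folds))
    for f, (train_runs, test_runs) in enumerate(cv.folds):
        tr = np.isin(run_ids, train_runs)
        te = np.isin(run_ids, test_runs)
        if not tr.any() or not te.any():
            raise InvalidFoldError(f"fold {f} has an empty train or test set")
        Ytr = Y[:, tr]
        if np.any(Ytr.min(axis=1) == Ytr.max(axis=1)):
            raise InvalidFoldError(f"fold {f} training set contains a single class")
        W = _fit_logreg_newton_batch(X[tr], Ytr, lam)
        z = W[:, 0][:, None] + W[:, 1:] @ X[te].T  # (B, n_test)
        pred = (z > 0).astype(float)  # tie (z == 0, p = 0.5) -> smaller class
        fold_accs[:, f] = (pred == score_against[:, te]).mean(axis=1)
    mean_accs = fold_accs.mean(axis=1)
    if per_fold:
        return mean_accs, fold_accs
    return mean_accs


# --------------------------------------------------------------------------
# Gaussian Naive Bayes
# --------------------------------------------------------------------------


def gnb_fit_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    var_floor: float = VAR_FLOOR,
    pooled_variance: bool = True,
) -> np.ndarray:
    """Gaussian Naive Bayes prediction with pooled within-class variance.

    Per voxel, class-conditional Gaussians share a pooled within-class
    variance (floored at ``var_floor``); class priors come from training
    frequencies; exact score ties resolve to the lexicographically smaller
    class label.
    """
    train_y = np.asarray(train_y)
    classes = sorted(np.unique(train_y).tolist())
    counts = np.array([(train_y == c).sum() for c in classes])
    if np.any(counts < 2):
        raise InvalidFoldError(f"need >= 2 training trials per class, got {counts.tolist()}")
    means = np.stack([train_X[train_y == c].mean(axis=0) for c in classes])
    if pooled_variance:
        ssw = sum(
            ((train_X[train_y == c] - means[i]) ** 2).sum(axis=0)
            for i, c in enumerate(classes)
        )
        var = ssw / (train_y.size - len(classes))
        var = np.broadcast_to(var, means.shape).copy()
    else:
        var = np.stack([train_X[train_y == c].var(axis=0, ddof=1) for c in classes])
    floored = var < var_floor
    if floored.any(axis=0).mean() > 0.5:
        warnings.warn("variance floor triggered on more than half of the voxels")
    var = np.maximum(var, var_floor)

    log_prior = np.log(counts / train_y.size)
    # (n_test, n_classes) summed log likelihood + log prior
    scores = np.stack(
        [
            -0.5 * (((test_X - means[i]) ** 2) / var[i] + np.log(2 * np.pi * var[i])).sum(axis=1)
            + log_prior[i]
            for i in range(len(classes))
        ],
        axis=1,
    )
    pred_idx = scores.argmax(axis=1)  # argmax takes the first (smaller) label on ties
    return np.asarray(classes, dtype=object)[pred_idx]


# --------------------------------------------------------------------------
# Searchlight
# --------------------------------------------------------------------------


@dataclass
class AccuracyMap:
    """Per-voxel searchlight decoding accuracy with a valid-center mask."""

    data: np.ndarray  # (X, Y, Z) accuracies, NaN outside valid centers
    valid: np.ndarray  # boolean (X, Y, Z)
    cube_edge: int
    code: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape != self.valid.shape:
            raise ShapeError("accuracy data and valid mask shapes differ")
        if np.isfinite(self.data[~self.valid]).any():
            raise ShapeError("accuracy values present outside the valid-center mask")

    def to_nifti(self, path, voxel_size_mm: float = 1.0) -> None:
        import nibabel as nib

        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))


def _box_sum(arr: np.ndarray, edge: int) -> np.ndarray:
    """Sum over the edge^3 cube centred at each voxel (zero padded)."""
    size = (1,) * (arr.ndim - 3) + (edge, edge, edge)
    return ndimage.uniform_filter(arr, size=size, mode="constant", cval=0.0) * edge**3


def searchlight_accuracy_map(
    stack: np.ndarray,
    labels: np.ndarray,
    run_ids: np.ndarray,
    mask: np.ndarray,
    cube_edge: int,
    cv: CVScheme,
    code: str = "category",
    var_floor: float = VAR_FLOOR,
) -> AccuracyMap:
    """GNB cubic-searchlight accuracy map under run-pair cross-validation.

    ``stack`` is (n_trials, X, Y, Z). For every in-mask centre, the features
    are the in-mask voxels of the edge^3 cube around it (clipped at volume
    borders); centres whose cube retains fewer than half of edge^3 in-mask
    voxels are marked invalid. The per-centre classifier is exactly
    :func:`gnb_fit_predict` with pooled variance; the mean accuracy across
    folds is assigned to the centre voxel.
    """
    if cube_edge % 2 != 1 or cube_edge < 1:
        raise InvalidArgumentError(f"cube_edge must be odd and >= 1, got {cube_edge}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidArgumentError("mask is empty")
    if stack.shape[1:] != mask.shape:
        raise ShapeError(f"stack grid {stack.shape[1:]} != mask shape {mask.shape}")
    labels = np.asarray(labels)
    classes = _binary_classes(labels)

    counts = _box_sum(mask.astype(float), cube_edge)
    valid = mask & (np.round(counts) >= cube_edge**3 / 2.0)

    maskf = mask.astype(float)
    acc_sum = np.zeros(mask.shape)
    for train_runs, test_runs in cv.folds:
        tr = np.isin(run_ids, train_runs)
        te = np.isin(run_ids, test_runs)
        ytr = labels[tr]
        for c, cnt in zip(*np.unique(ytr, return_counts=True)):
            if cnt < 2:
                raise InvalidFoldError(f"class {c!r} has {cnt} training trials in a fold")
        Xtr = stack[tr]
        Xte = stack[te]
        mu = [Xtr[ytr == c].mean(axis=0) for c in classes]
        n0, n1 = (ytr == classes[0]).sum(), (ytr == classes[1]).sum()
        ssw = ((Xtr[ytr == classes[0]] - mu[0]) ** 2).sum(axis=0) + (
            (Xtr[ytr == classes[1]] - mu[1]) ** 2
        ).sum(axis=0)
        var = np.maximum(ssw / (ytr.size - 2), var_floor)
        # per-voxel log-likelihood difference (class0 - class1); the pooled
        # log-variance term cancels between classes
        d = -0.5 * ((Xte - mu[0]) ** 2 - (Xte - mu[1]) ** 2) / var
        d *= maskf  # out-of-mask voxels contribute nothing
        d_sum = _box_sum(d, cube_edge)
        prior_diff = np.log(n0 / ytr.size) - np.log(n1 / ytr.size)
        pred_is_c0 = (d_sum + prior_diff) >= 0.0  # tie -> smaller label
        truth_is_c0 = (labels[te] == classes[0])[:, None, None, None]
        acc_sum += (pred_is_c0 == truth_is_c0).mean(axis=0)

    acc = acc_sum / cv.n_folds
    data = np.where(valid, acc, np.nan)
    return AccuracyMap(data=data, valid=valid, cube_edge=cube_edge, code=code)


def searchlight_accuracy_maps_batch(
    stack: np.ndarray,
    label_matrix: np.ndarray,
    run_ids: np.ndarray,
    mask: np.ndarray,
    cube_edge: int,
    cv: CVScheme,
    code: str = "category",
    var_floor: float = VAR_FLOOR,
    chunk: int = 32,
) -> list[AccuracyMap]:
    """Searchlight maps for B label vectors sharing one trial stack.

    Equivalent to calling :func:`searchlight_accuracy_map` once per row of
    ``label_matrix`` (the invariant is tested), but the Gaussian Naive Bayes
    sufficient statistics are computed for all label vectors at once: class
    means are matrix products of label indicators with the trial stack, and
    the pooled within-class variance uses the label-independent sum of
    squares. Used for permutation null maps, where hundreds of label vectors
    share the data.
    """
    if cube_edge % 2 != 1 or cube_edge < 1:
        raise InvalidArgumentError(f"cube_edge must be odd and >= 1, got {cube_edge}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidArgumentError("mask is empty")
    label_matrix = np.asarray(label_matrix)
    B, n = label_matrix.shape
    if stack.shape[0] != n:
        raise ShapeError("label matrix and stack must align")
    classes = _binary_classes(label_matrix[0])
    grid = stack.shape[1:]
    nvox = int(np.prod(grid))
    flat = stack.reshape(n, nvox)
    maskf = mask.astype(float).ravel()

    counts = _box_sum(mask.astype(float), cube_edge)
    valid = mask & (np.round(counts) >= cube_edge**3 / 2.0)

    acc_sum = np.zeros((B,) + grid)
    for train_runs, test_runs in cv.folds:
        tr = np.isin(run_ids, train_runs)
        te = np.isin(run_ids, test_runs)
        Y0 = (label_matrix[:, tr] == classes[0]).astype(float)  # (B, n_train)
        n0 = Y0.sum(axis=1)
        n1 = tr.sum() - n0
        if np.any(n0 < 2) or np.any(n1 < 2):
            raise InvalidFoldError("every class needs >= 2 training trials per fold")
        Xtr = flat[tr]
        Xte = flat[te]
        S2 = (Xtr**2).sum(axis=0)  # label independent
        sum0 = Y0 @ Xtr  # (B, nvox)
        sum_all = Xtr.sum(axis=0)
        mu0 = sum0 / n0[:, None]
        mu1 = (sum_all[None, :] - sum0) / n1[:, None]
        ssw = S2[None, :] - n0[:, None] * mu0**2 - n1[:, None] * mu1**2
        var = np.maximum(ssw / (tr.sum() - 2), var_floor)
        w = (mu0 - mu1) / var
        c = w * (mu0 + mu1) / 2.0
        # per-voxel log-likelihood difference d_bjv = w_bv * x_jv - c_bv
        prior_diff = np.log(n0 / tr.sum()) - np.log(n1 / tr.sum())
        truth_is_c0 = label_matrix[:, te] == classes[0]  # (B, n_test)
        for b0 in range(0, B, chunk):
            b1 = min(b0 + chunk, B)
            d = w[b0:b1, None, :] * Xte[None, :, :] - c[b0:b1, None, :]
            d *= maskf
            d_sum = _box_sum(d.reshape(b1 - b0, Xte.shape[0], *grid), cube_edge)
            pred_is_c0 = d_sum + prior_diff[b0:b1, None, None, None, None] >= 0.0
            match = pred_is_c0 == truth_is_c0[b0:b1, :, None, None, None]
            acc_sum[b0:b1] += match.mean(axis=1)
    acc = acc_sum / cv.n_folds
    maps = []
    for b in range(B):
        data = np.where(valid, acc[b], np.nan)
        maps.append(AccuracyMap(data=data, valid=valid.copy(), cube_edge=cube_edge, code=code))
    return maps


def patternset_to_stack(ps: PatternSet, grid_dims: tuple[int, int, int]) -> np.ndarray:
    """Scatter a PatternSet back onto its grid as an (n_trials, X, Y, Z) stack."""
    stack = np.zeros((ps.n_trials,) + tuple(grid_dims))
    idx = tuple(ps.voxels.T)
    stack[(slice(None),) + idx] = ps.X
    return stack
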