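"""Nonparametric group inference for decoding analyses.

Three tiers, all resampling-based:

1. *Above-chance ROI decoding*: pre-generated within-run label permutations
   give a per-subject null accuracy distribution; subject nulls are averaged
   permutation-by-permutation into a group null, and the empirical p-value is
   the fraction of the null exceeding the observed group mean.
2. *Condition differences*: the same matched permutation sets in both
   disruption conditions give a null distribution of condition differences
   (control minus disrupted, averaged across subjects).
3. *Whole-brain searchlight differences*: per-subject null difference maps
   are bootstrapped into group null maps; voxels pass where the true group
   difference exceeds the voxelwise (1 - alpha) null quantile, and
   face-connected clusters survive if larger than the (1 - alpha) quantile
   of null maximum cluster sizes.

Also here: FDR-based functional ROI definition from accuracy maps, Gaussian
map smoothing with invalid-voxel handling, Spearman correlation with an
exact small-sample permutation p, and a median-split Welch t-test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .decode import CVScheme, cv_accuracy_batch
from .errors import (
    AlignmentError,
    InsufficientGroupError,
    InvalidArgumentError,
    ShapeError,
    UndefinedCorrelationError,
)
from .preprocess import PatternSet

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# --------------------------------------------------------------------------
# Label permutations
# --------------------------------------------------------------------------


@dataclass
class PermutationSet:
    """Pre-generated within-run label shuffles, reusable across analyses."""

    perms: np.ndarray  # (n_perm, n_trials) label array
    seed: int
    set_id: str
    run_ids: np.ndarray

    @property
    def n_perm(self) -> int:
        return self.perms.shape[0]


def generate_label_permutations(
    labels: np.ndarray, run_ids: np.ndarray, n_perm: int, seed: int
) -> PermutationSet:
    """Draw ``n_perm`` independent within-run shuffles of ``labels``.

    Run membership is preserved (runs are the exchangeability blocks given
    per-run z-scoring), per-run label counts are invariant, and the identity
    permutation is excluded when any non-identity shuffle exists.
    """
    if n_perm < 1:
        raise InvalidArgumentError(f"n_perm must be >= 1, got {n_perm}")
    labels = np.asarray(labels)
    run_ids = np.asarray(run_ids)
    if labels.shape != run_ids.shape:
        raise ShapeError("labels and run_ids must have the same length")
    rng = np.random.default_rng(seed)
    run_index = [np.flatnonzero(run_ids == r) for r in pd_unique(run_ids)]
    for idx in run_index:
        if idx.size == 1:
            warnings.warn("a run has a single trial; its shuffle is a no-op")
    shufflable = any(np.unique(labels[idx]).size > 1 for idx in run_index)
    perms = np.empty((n_perm, labels.size), dtype=labels.dtype)
    for k in range(n_perm):
        for _ in range(1000):
            perm = labels.copy()
            for idx in run_index:
                perm[idx] = labels[idx][rng.permutation(idx.size)]
            if not shufflable or not np.array_equal(perm, labels):
                break
        perms[k] = perm
    set_id = f"seed={seed},n={n_perm},trials={labels.size}"
    return PermutationSet(perms=perms, seed=seed, set_id=set_id, run_ids=run_ids)


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, first = np.unique(values, return_index=True)
    return values[np.sort(first)]


# --------------------------------------------------------------------------
# ROI permutation inference
# --------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Resampled statistic values against which an observation is ranked."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise InvalidArgumentError("empty null distribution")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("null distribution contains non-finite values")


def roi_group_null(
    pattern_sets: list[PatternSet],
    cv_schemes: list[CVScheme],
    perm_sets: list[PermutationSet],
    code: str,
    lam: float = 1.0,
) -> tuple[NullDistribution, np.ndarray]:
    """Group-mean null accuracies from matched per-subject permutations.

    For permutation k, each subject's classifier is retrained and tested with
    permuted labels; the subject accuracies are averaged into one group value.
    Returns the group null and the (n_subjects, n_perm) per-subject nulls.
    """
    if not (len(pattern_sets) == len(cv_schemes) == len(perm_sets)):
        raise AlignmentError("one pattern set, cv scheme and permutation set per subject")
    n_perm = perm_sets[0].n_perm
    for ps in perm_sets:
        if ps.n_perm != n_perm:
            raise AlignmentError("all subjects must share the same number of permutations")
    subject_nulls = np.empty((len(pattern_sets), n_perm))
    for s, (patterns, cv, perms) in enumerate(zip(pattern_sets, cv_schemes, perm_sets)):
        subject_nulls[s] = cv_accuracy_batch(
            patterns.X, perms.perms, patterns.run_ids(), cv, lam
        )
    group = subject_nulls.mean(axis=0)
    return NullDistribution(group, kind="group-mean-accuracy"), subject_nulls


def empirical_p(
    null: NullDistribution | np.ndarray, observed: float, rule: str = "greater"
) -> float:
    """Fraction of the null distribution exceeding the observed statistic.

    ``rule='greater'`` is the plain count #{null > observed}/n (an observed
    value above every null value yields p = 0); ``rule='add_one'`` uses the
    (k + 1)/(n + 1) variant that never returns 0.
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null, float)
    if values.size == 0:
        raise InvalidArgumentError("empty null distribution")
    k = int((values > observed).sum())
    if rule == "greater":
        return k / values.size
    if rule == "add_one":
        return (k + 1) / (values.size + 1)
    raise InvalidArgumentError(f"unknown rule {rule!r}")


@dataclass
class DifferenceTestResult:
    observed_difference: float
    null: NullDistribution
    p_value: float


def tms_difference_test(
    ctrl_nulls: np.ndarray,
    disrupted_nulls: np.ndarray,
    ctrl_observed: np.ndarray,
    disrupted_observed: np.ndarray,
) -> DifferenceTestResult:
    """Matched-permutation test of control-minus-disrupted decoding accuracy.

    Null difference k averages (control null[k] - disrupted null[k]) over
    subjects, which requires the same pre-generated permutation sets in both
    conditions; p is the fraction of null differences exceeding the observed
    group-mean difference.
    """
    ctrl_nulls = np.atleast_2d(np.asarray(ctrl_nulls, float))
    dis_nulls = np.atleast_2d(np.asarray(disrupted_nulls, float))
    if ctrl_nulls.shape != dis_nulls.shape:
        raise AlignmentError(
            f"permutation null shapes differ: {ctrl_nulls.shape} vs {dis_nulls.shape}"
        )
    ctrl_obs = np.atleast_1d(np.asarray(ctrl_observed, float))
    dis_obs = np.atleast_1d(np.asarray(disrupted_observed, float))
    if ctrl_obs.size != ctrl_nulls.shape[0] or dis_obs.size != ctrl_obs.size:
        raise AlignmentError("observed accuracies must align with the null matrices")
    null_diff = (ctrl_nulls - dis_nulls).mean(axis=0)
    obs_diff = float((ctrl_obs - dis_obs).mean())
    null = NullDistribution(null_diff, kind="condition-difference")
    return DifferenceTestResult(obs_diff, null, empirical_p(null, obs_diff))


# --------------------------------------------------------------------------
# Map smoothing and functional ROI definition
# --------------------------------------------------------------------------


def smooth_gaussian(map3d: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing with normalized masked convolution.

    NaN voxels (invalid searchlight centres) are excluded from the kernel
    mass and stay NaN in the output; ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise InvalidArgumentError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    map3d = np.asarray(map3d, dtype=float)
    if fwhm_mm == 0:
        return map3d.copy()
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    valid = np.isfinite(map3d)
    num = ndimage.gaussian_filter(np.where(valid, map3d, 0.0), sigma, mode="constant")
    den = ndimage.gaussian_filter(valid.astype(float), sigma, mode="constant")
    out = np.full_like(map3d, np.nan)
    ok = valid & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return out


def define_functional_rois(
    subject_maps: np.ndarray, q: float = 0.0001, chance: float = 0.5
) -> tuple[np.ndarray, np.ndarray, dict]:
    """FDR-thresholded group mask of above-chance decoding accuracy.

    Per voxel valid in every subject, a one-sample t-test (one-sided,
    greater) of subject accuracies against chance; Benjamini-Hochberg over
    valid voxels at level ``q``. Returns the surviving mask, the group-mean
    accuracy map within the mask (NaN elsewhere), and diagnostics.
    """
    maps = np.asarray(subject_maps, dtype=float)
    S = maps.shape[0]
    if S < 3:
        raise InvalidArgumentError(f"need >= 3 subjects, got {S}")
    if not 0 < q <= 1:
        raise InvalidArgumentError(f"FDR level must be in (0, 1], got {q}")
    valid = np.isfinite(maps).all(axis=0)
    sd = np.zeros(maps.shape[1:])
    sd[valid] = maps[:, valid].std(axis=0, ddof=1)
    degenerate = valid & (sd == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} voxels have zero across-subject variance; excluded"
        )
    testable = valid & (sd > 0)
    mask = np.zeros(maps.shape[1:], dtype=bool)
    if testable.any():
        vals = maps[:, testable]
        t = (vals.mean(axis=0) - chance) / (vals.std(axis=0, ddof=1) / np.sqrt(S))
        p = stats.t.sf(t, df=S - 1)
        p_adj = stats.false_discovery_control(p, method="bh")
        mask[testable] = p_adj <= q
    mean_map = np.where(mask, maps.mean(axis=0), np.nan)
    info = {"n_tested": int(testable.sum()), "n_excluded_degenerate": int(degenerate.sum())}
    return mask, mean_map, info


# --------------------------------------------------------------------------
# Clusters
# --------------------------------------------------------------------------

FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3)
    size: int
    center_of_mass: tuple[float, float, float]
    survives: bool = False


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    voxel_threshold: float | None = None
    cluster_size_threshold: float | None = None
    meta: dict = field(default_factory=dict)

    def surviving(self) -> list[Cluster]:
        return [c for c in self.clusters if c.survives]

    def max_size(self) -> int:
        return max((c.size for c in self.clusters), default=0)


def extract_clusters(binary_map: np.ndarray) -> ClusterReport:
    """Face-connected (6-neighbourhood) components of a boolean 3-D map."""
    binary_map = np.asarray(binary_map, dtype=bool)
    if binary_map.ndim != 3:
        raise ShapeError(f"expected a 3-D map, got shape {binary_map.shape}")
    labeled, n = ndimage.label(binary_map, structure=FACE_CONNECTIVITY)
    clusters = []
    for i in range(1, n + 1):
        voxels = np.argwhere(labeled == i)
        clusters.append(
            Cluster(
                voxels=voxels,
                size=voxels.shape[0],
                center_of_mass=tuple(voxels.mean(axis=0)),
            )
        )
    clusters.sort(key=lambda c: -c.size)
    return ClusterReport(clusters=clusters)


def _max_cluster_size(binary_map: np.ndarray) -> int:
    labeled, n = ndimage.label(binary_map, structure=FACE_CONNECTIVITY)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


# --------------------------------------------------------------------------
# Bootstrap searchlight group inference
# --------------------------------------------------------------------------


def searchlight_group_difference(
    true_maps: np.ndarray,
    null_maps: np.ndarray,
    n_boot: int,
    voxel_alpha: float = 0.005,
    cluster_alpha: float = 0.005,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, ClusterReport]:
    """Bootstrap group inference on searchlight difference maps.

    ``true_maps`` is (S, X, Y, Z): per-subject smoothed control-minus-
    disrupted accuracy difference maps. ``null_maps`` is (S, n_null, X, Y, Z):
    the same quantity computed from permuted labels, smoothed identically.

    Procedure: ``n_boot`` group null maps are formed by drawing one null map
    per subject uniformly with replacement and averaging across subjects. A
    voxel of the true group-mean map passes if its value exceeds the fraction
    (1 - voxel_alpha) of its bootstrap null values. Passing voxels form
    face-connected clusters; each null group map is thresholded by the same
    per-voxel rule and its maximum cluster size recorded; an observed cluster
    survives if its size exceeds (1 - cluster_alpha) of the null maxima.
    """
    true_maps = np.asarray(true_maps, dtype=float)
    null_maps = np.asarray(null_maps, dtype=float)
    if true_maps.ndim != 4 or null_maps.ndim != 5:
        raise ShapeError("true_maps must be (S, X, Y, Z) and null_maps (S, n_null, X, Y, Z)")
    if null_maps.shape[0] != true_maps.shape[0] or null_maps.shape[2:] != true_maps.shape[1:]:
        raise ShapeError(
            f"grid/subject mismatch: true {true_maps.shape}, null {null_maps.shape}"
        )
    S = true_maps.shape[0]
    n_null = null_maps.shape[1]
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; bootstrap quantiles will be unstable")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    grid = true_maps.shape[1:]
    valid = np.isfinite(true_maps).all(axis=0) & np.isfinite(null_maps).all(axis=(0, 1))
    true_group = true_maps.mean(axis=0)

    nv = int(valid.sum())
    null_flat = null_maps[:, :, valid]  # (S, n_null, nv)
    draws = rng.integers(0, n_null, size=(n_boot, S))
    boot = np.zeros((n_boot, nv), dtype=np.float64)
    for s in range(S):
        boot += null_flat[s][draws[:, s]]
    boot /= S

    tv = true_group[valid]
    need = 1.0 - voxel_alpha
    # observed voxelwise test: fraction of bootstrap values strictly below
    pass_frac = (boot < tv[None, :]).mean(axis=0)
    voxel_pass = pass_frac >= need

    sig = np.zeros(grid, dtype=bool)
    sig[valid] = voxel_pass
    report = extract_clusters(sig)

    # null maximum cluster sizes, each null group map thresholded by the same
    # per-voxel quantile rule (rank within the bootstrap distribution)
    order = boot.argsort(axis=0, kind="stable")
    ranks = np.empty_like(order)
    put = np.arange(n_boot)[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(put, order.shape), axis=0)
    null_pass = ranks / n_boot >= need  # (n_boot, nv)
    max_sizes = np.zeros(n_boot, dtype=int)
    any_pass = null_pass.any(axis=1)
    scratch = np.zeros(grid, dtype=bool)
    for m in np.flatnonzero(any_pass):
        scratch[:] = False
        scratch[valid] = null_pass[m]
        max_sizes[m] = _max_cluster_size(scratch)

    for cluster in report.clusters:
        cluster.survives = (max_sizes < cluster.size).mean() >= 1.0 - cluster_alpha
    report.voxel_threshold = float(need)
    report.cluster_size_threshold = float(np.quantile(max_sizes, 1.0 - cluster_alpha))
    report.meta = {
        "n_boot": int(n_boot),
        "n_null_per_subject": int(n_null),
        "n_subjects": int(S),
        "null_max_cluster_sizes_quantiles": {
            "q50": float(np.quantile(max_sizes, 0.5)),
            "q99": float(np.quantile(max_sizes, 0.99)),
        },
    }
    surviving = np.zeros(grid, dtype=bool)
    for cluster in report.surviving():
        surviving[tuple(cluster.voxels.T)] = True
    return surviving, report


# --------------------------------------------------------------------------
# Behavioral statistics
# --------------------------------------------------------------------------


def spearman_corr(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p for small n.

    Average ranks handle ties. For n <= ``exact_max_n`` the two-sided p-value
    comes from the exhaustive permutation distribution of the rank
    correlation; for larger n the usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise InvalidArgumentError("need paired vectors of length >= 4")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedCorrelationError("rank correlation undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    rho = float((rxc * ryc).sum() / denom)
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_null = (ryc[perms] @ rxc) / denom
        p = float((np.abs(rho_null) >= abs(rho) - 1e-12).mean())
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def median_split_welch(
    decrements: np.ndarray, effects: np.ndarray
) -> tuple[float, float, float]:
    """Welch t-test of a decoding metric between median-split halves.

    Subjects are split at the median behavioral decrement (stable sort:
    tied values fall to the most-impaired half; with odd n the median subject
    is excluded). Returns (t, Welch df, two-sided p) for most-impaired minus
    least-impaired.
    """
    decrements = np.asarray(decrements, dtype=float)
    effects = np.asarray(effects, dtype=float)
    n = decrements.size
    if n < 4 or effects.size != n:
        raise InvalidArgumentError("need paired vectors of length >= 4")
    order = np.argsort(decrements, kind="stable")
    half = n // 2
    if n % 2 == 0:
        least, most = order[:half], order[half:]
    else:
        least, most = order[:half], order[half + 1 :]
    if least.size < 2 or most.size < 2:
        raise InsufficientGroupError("each median-split group needs >= 2 subjects")
    a, b = effects[most], effects[least]
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = float((a.mean() - b.mean()) / math.sqrt(se2))
    df = float(se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return t, df, p
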