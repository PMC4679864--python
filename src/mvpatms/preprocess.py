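"""Nuisance GLM, baseline subtraction, temporal z-scoring, pattern extraction.

Mirrors a standard event-related preprocessing chain: an ordinary
least-squares regression with HRF-convolved stimulus regressors (one per
stimulus-category x task-condition combination present in the run), six
motion regressors and an order-0..5 orthogonal polynomial baseline; the
fitted nuisance component (motion + polynomials) is subtracted, each run is
z-scored temporally voxel-wise, and single-trial patterns are read out from
the one volume falling inside a code-specific lag window after stimulus
onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hrf
from .errors import (
    AmbiguousWindowError,
    EmptyDesignError,
    InvalidArgumentError,
    RankDeficiencyError,
    ShapeError,
)
from .synth import EventTable, MotionParams, Volume4D

# lag windows (seconds after stimulus onset) used to read out each code
CATEGORY_LAG_S = (5.0, 6.0)
RELEVANCE_LAG_S = (6.0, 7.0)

POLY_ORDER = 5
SD_FLOOR = 1e-12


@dataclass
class DesignMatrix:
    """T x P design with labeled columns and roles (stimulus/motion/poly)."""

    matrix: np.ndarray
    names: list[str]
    roles: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names) or len(self.names) != len(self.roles):
            raise ShapeError("design matrix columns, names and roles must align")

    def columns(self, role: str) -> np.ndarray:
        idx = [i for i, r in enumerate(self.roles) if r == role]
        return self.matrix[:, idx]

    def nuisance_index(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r in ("motion", "poly")])


def orthogonal_polynomials(T: int, order: int = POLY_ORDER) -> np.ndarray:
    """Discrete orthonormal polynomial basis, orders 0..order, over T samples.

    Built by QR on a Legendre Vandermonde matrix so the columns are mutually
    orthogonal on the actual sample grid (Legendre polynomials are only
    orthogonal in the continuum limit).
    """
    if T <= order:
        raise InvalidArgumentError(f"need T > polynomial order, got T={T}, order={order}")
    u = np.linspace(-1.0, 1.0, T)
    V = np.polynomial.legendre.legvander(u, order)
    Q, R = np.linalg.qr(V)
    # fix sign so each column correlates positively with its Legendre parent
    return Q * np.sign(np.diag(R))


def build_design_matrix(
    events: EventTable, motion: MotionParams, T: int, tr_s: float, t0_s: float = 0.0
) -> DesignMatrix:
    """Stimulus + motion + polynomial design for one run."""
    if len(events.table) == 0:
        raise EmptyDesignError("event table has no trials; stimulus block would be empty")
    if motion.data.shape[0] != T:
        raise ShapeError(f"motion has {motion.data.shape[0]} rows but T={T}")

    cols, names, roles = [], [], []
    for category in sorted(events.table["category"].unique()):
        onsets = events.table.loc[events.table["category"] == category, "onset"].to_numpy()
        durations = events.table.loc[events.table["category"] == category, "duration"]
        reg = hrf.stimulus_regressor(onsets, float(durations.iloc[0]), T, tr_s, t0_s=t0_s)
        cols.append(reg)
        names.append(f"stim_{category}_{events.condition}")
        roles.append("stimulus")

    for j, name in enumerate(["x", "y", "z", "roll", "pitch", "yaw"]):
        cols.append(motion.data[:, j])
        names.append(f"motion_{name}")
        roles.append("motion")

    P = orthogonal_polynomials(T)
    for k in range(P.shape[1]):
        cols.append(P[:, k])
        names.append(f"poly_{k}")
        roles.append("poly")

    X = np.column_stack(cols)
    zero = [names[i] for i in range(X.shape[1]) if np.allclose(X[:, i], 0.0)]
    if zero:
        raise EmptyDesignError(f"all-zero design columns: {zero}")
    return DesignMatrix(matrix=X, names=names, roles=roles)


def _check_rank(X: DesignMatrix) -> None:
    M = X.matrix
    norms = np.linalg.norm(M, axis=0)
    Q, R = np.linalg.qr(M / norms)
    bad = np.abs(np.diag(R)) < 1e-10
    if bad.any():
        culprits = [X.names[i] for i in np.flatnonzero(bad)]
        raise RankDeficiencyError(f"design is rank deficient; collinear columns: {culprits}")


def residualize_baseline(vol: Volume4D, X: DesignMatrix) -> Volume4D:
    """OLS fit of the full design; subtract the fitted motion + polynomial
    component, retaining stimulus-locked signal."""
    if X.matrix.shape[0] != vol.n_vols:
        raise ShapeError(f"design has T={X.matrix.shape[0]} but volume has T={vol.n_vols}")
    _check_rank(X)
    Y = vol.data.reshape(-1, vol.n_vols).T  # (T, nvox)
    beta, *_ = np.linalg.lstsq(X.matrix, Y, rcond=None)
    nuis = X.nuisance_index()
    baseline = X.matrix[:, nuis] @ beta[nuis]
    out = (Y - baseline).T.reshape(vol.data.shape)
    meta = dict(vol.meta)
    meta["glm_beta"] = beta  # (P, nvox), column order of X.names
    meta["glm_names"] = list(X.names)
    return Volume4D(out, vol.voxel_size_mm, vol.tr_s, vol.t0_s, meta)


def zscore_run(vol: Volume4D) -> Volume4D:
    """Temporal z-scoring per voxel (mean 0, sample sd 1, ddof=1).

    Voxels whose temporal sd falls below a floor are zeroed and flagged in
    ``meta['degenerate_voxels']``.
    """
    if vol.n_vols < 2:
        raise InvalidArgumentError("z-scoring needs at least 2 volumes")
    data = vol.data
    mean = data.mean(axis=3, keepdims=True)
    sd = data.std(axis=3, ddof=1, keepdims=True)
    degenerate = sd[..., 0] < SD_FLOOR
    safe_sd = np.where(sd < SD_FLOOR, 1.0, sd)
    z = (data - mean) / safe_sd
    z[degenerate] = 0.0
    meta = dict(vol.meta)
    meta["degenerate_voxels"] = degenerate
    return Volume4D(z, vol.voxel_size_mm, vol.tr_s, vol.t0_s, meta)


@dataclass
class PatternSet:
    """Trials x voxels matrix with per-trial labels and voxel coordinates."""

    X: np.ndarray  # (n_trials, n_voxels)
    labels: pd.DataFrame  # category, relevance, run_id, condition, tms_condition
    voxels: np.ndarray  # (n_voxels, 3) grid indices
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != self.X.shape[0]:
            raise ShapeError("label rows must match trial count")
        if self.voxels.shape != (self.X.shape[1], 3):
            raise ShapeError("voxel coordinate list must be (n_voxels, 3)")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def label_vector(self, code: str) -> np.ndarray:
        if code not in ("category", "relevance"):
            raise InvalidArgumentError(f"unknown code {code!r}")
        return self.labels[code].to_numpy()

    def run_ids(self) -> np.ndarray:
        return self.labels["run_id"].to_numpy()

    @classmethod
    def concat(cls, parts: list["PatternSet"]) -> "PatternSet":
        if not parts:
            raise InvalidArgumentError("no pattern sets to concatenate")
        for p in parts[1:]:
            if not np.array_equal(p.voxels, parts[0].voxels):
                raise ShapeError("pattern sets cover different voxel sets")
        return cls(
            X=np.vstack([p.X for p in parts]),
            labels=pd.concat([p.labels for p in parts], ignore_index=True),
            voxels=parts[0].voxels,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), X=self.X, voxels=self.voxels)
        sidecar = {"labels": self.labels.to_dict(orient="list"), "meta": {}}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "PatternSet":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            X=arrays["X"], labels=pd.DataFrame(sidecar["labels"]), voxels=arrays["voxels"]
        )


def extract_trial_patterns(
    vol: Volume4D,
    events: EventTable,
    lag_window_s: tuple[float, float],
    mask: np.ndarray,
) -> PatternSet:
    """Single-volume trial patterns at a code-specific post-onset lag.

    For each trial the unique volume whose acquisition start time t satisfies
    ``onset + low <= t < onset + high`` is selected; with TR 1 s and integer
    onsets and a 1 s window this volume is unique by construction.
    """
    low, high = lag_window_s
    if not high > low:
        raise InvalidArgumentError(f"lag window must have high > low, got {lag_window_s}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.grid_dims:
        raise ShapeError(f"mask shape {mask.shape} != volume grid {vol.grid_dims}")
    times = vol.vol_times()
    rows = []
    for onset in events.onsets():
        sel = np.flatnonzero((times >= onset + low) & (times < onset + high))
        if sel.size != 1:
            raise AmbiguousWindowError(
                f"lag window {lag_window_s} selects {sel.size} volumes for onset "
                f"{onset} s at TR {vol.tr_s} s (run has {vol.n_vols} volumes)"
            )
        rows.append(vol.data[..., sel[0]][mask])
    labels = pd.DataFrame(
        {
            "category": events.table["category"].to_numpy(),
            "relevance": events.relevance_labels(),
            "run_id": events.run_id,
            "condition": events.condition,
            "tms_condition": events.tms_condition,
        }
    )
    return PatternSet(X=np.array(rows), labels=labels, voxels=np.argwhere(mask))


def preprocess_run(
    vol: Volume4D, events: EventTable, motion: MotionParams
) -> Volume4D:
    """Full per-run chain: nuisance GLM residualization then z-scoring."""
    X = build_design_matrix(events, motion, vol.n_vols, vol.tr_s, vol.t0_s)
    return zscore_run(residualize_baseline(vol, X))


def patterns_from_runs(
    runs: list,
    lag_window_s: tuple[float, float],
    mask: np.ndarray,
) -> PatternSet:
    """Preprocess a list of SimulatedRun objects and stack their patterns."""
    parts = []
    for run in runs:
        clean = preprocess_run(run.volume, run.events, run.motion)
        parts.append(extract_trial_patterns(clean, run.events, lag_window_s, mask))
    return PatternSet.concat(parts)
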