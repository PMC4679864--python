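"""Synthetic BOLD cohort generator with planted multivoxel codes.

Emulates a two-session working-memory experiment: per subject and disruption
condition (``control`` vs ``disrupted``), five "Remember Faces" and five
"Remember Scenes" runs of 20 one-back trials each (600 ms stimuli, onset
jitter 3/5/7 s, TR 1 s, four one-back matches per run). Two multivoxel codes
are planted in designated voxel regions:

* a *stimulus category* code (face = +1, scene = -1), and
* a *goal relevance* code (relevant = +1, irrelevant = -1), where a stimulus
  is relevant iff its category matches the run's task condition.

In the disrupted condition the planted code amplitudes inside designated
regions are multiplied by per-region attenuation factors in [0, 1], the
operational analogue of transient cortical disruption read out as a loss of
decoding accuracy. Per-subject behavioral accuracy is linked positively to
the subject's (undisrupted) relevance-code amplitude in a designated region.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hrf
from .errors import (
    DesignInfeasibleError,
    InvalidArgumentError,
    ShapeError,
    UnknownRegionError,
)

CONTROL = "control"
DISRUPTED = "disrupted"
TMS_CONDITIONS = (CONTROL, DISRUPTED)
REMEMBER_FACES = "remember_faces"
REMEMBER_SCENES = "remember_scenes"
TASK_CONDITIONS = (REMEMBER_FACES, REMEMBER_SCENES)
FACE = "face"
SCENE = "scene"

EVENT_COLUMNS = ["onset", "duration", "category", "match", "correct"]
MOTION_COLUMNS = ["x", "y", "z", "roll", "pitch", "yaw"]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class BehaviorModel:
    """Linear link from planted relevance amplitude to task accuracy.

    accuracy = baseline + slope * (subject amplitude in `region`) + noise,
    minus `disrupted_decrement` in the disrupted condition, clipped to [0, 1].
    """

    baseline: float = 0.83
    slope: float = 0.50
    noise_sd: float = 0.02
    disrupted_decrement: float = 0.028
    region: str = "relevance_region"


def default_regions(grid_dims: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Two disjoint 3x3x3 cuboid regions at opposite corners of the grid."""
    dims = tuple(int(d) for d in grid_dims)
    if min(dims) < 8:
        raise InvalidArgumentError(
            f"default regions need grid dims >= 8, got {dims}; pass explicit regions"
        )
    regions = {}
    cat = np.zeros(dims, dtype=bool)
    cat[1:4, 1:4, 1:4] = True
    rel = np.zeros(dims, dtype=bool)
    rel[dims[0] - 4 : dims[0] - 1, dims[1] - 4 : dims[1] - 1, dims[2] - 4 : dims[2] - 1] = True
    regions["category_region"] = cat
    regions["relevance_region"] = rel
    return regions


@dataclass
class SimConfig:
    """Full description of a simulated cohort, including its seed.

    Code patterns (``category_code`` / ``relevance_code``) map region ids to
    either a scalar amplitude — expanded to a random-sign, constant-magnitude
    voxel pattern — or an explicit per-voxel amplitude array over the region's
    voxels. Amplitudes are in units of the (pre z-scoring) noise standard
    deviation when ``noise_sd`` is 1.
    """

    n_subjects: int = 8
    runs_per_condition: int = 5
    trials_per_run: int = 20
    matches_per_run: int = 4
    iti_choices_s: tuple[float, ...] = (3.0, 5.0, 7.0)
    stim_duration_s: float = 0.6
    tr_s: float = 1.0
    pre_task_rest_s: float = 4.0
    post_task_rest_s: float = 12.0
    grid_dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: float = 3.5
    noise_sd: float = 1.0
    regions: dict[str, np.ndarray] | None = None
    category_code: dict[str, float | np.ndarray] = field(
        default_factory=lambda: {"category_region": 0.15}
    )
    relevance_code: dict[str, float | np.ndarray] = field(
        default_factory=lambda: {"relevance_region": 0.2}
    )
    disruption_factors: dict[str, float] = field(
        default_factory=lambda: {"category_region": 0.8, "relevance_region": 0.5}
    )
    drift_coeffs_range: float = 0.5
    drift_order: int = 3
    motion_sd: float = 0.05
    motion_coupling: float = 0.5
    subject_amp_sd: float = 0.25
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    max_intervening_irrelevant: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        self.iti_choices_s = tuple(float(g) for g in self.iti_choices_s)
        if self.regions is None:
            self.regions = default_regions(self.grid_dims)
        if isinstance(self.behavior, dict):
            self.behavior = BehaviorModel(**self.behavior)
        self.validate()

    def validate(self) -> None:
        if self.trials_per_run % 2 != 0:
            raise InvalidArgumentError("trials_per_run must be even (balanced classes)")
        relevant_per_run = self.trials_per_run // 2
        if self.matches_per_run > relevant_per_run - 1:
            raise DesignInfeasibleError(
                f"matches_per_run={self.matches_per_run} exceeds relevant trials - 1 "
                f"({relevant_per_run - 1})"
            )
        for rid, f in self.disruption_factors.items():
            if not 0.0 <= f <= 1.0:
                raise InvalidArgumentError(f"disruption factor for {rid!r} not in [0,1]: {f}")
        for code in (self.category_code, self.relevance_code, self.disruption_factors):
            for rid in code:
                if rid not in self.regions:
                    raise UnknownRegionError(rid)
        for rid, mask in self.regions.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.grid_dims:
                raise ShapeError(f"region {rid!r} mask shape {mask.shape} != {self.grid_dims}")
            self.regions[rid] = mask
        if self.tr_s <= 0 or self.stim_duration_s <= 0 or self.noise_sd < 0:
            raise InvalidArgumentError("tr_s/stim_duration_s must be > 0, noise_sd >= 0")


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------


@dataclass
class EventTable:
    """One run's trial list plus run-level attributes."""

    table: pd.DataFrame  # columns: onset, duration, category, match, correct
    condition: str  # remember_faces | remember_scenes
    run_id: str
    tms_condition: str  # control | disrupted

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ShapeError(f"event table missing columns {missing}")
        if self.condition not in TASK_CONDITIONS:
            raise InvalidArgumentError(f"unknown task condition {self.condition!r}")
        if self.tms_condition not in TMS_CONDITIONS:
            raise InvalidArgumentError(f"unknown tms condition {self.tms_condition!r}")

    @property
    def relevant_category(self) -> str:
        return FACE if self.condition == REMEMBER_FACES else SCENE

    def relevance_labels(self) -> np.ndarray:
        """'relevant' where category matches the run's task condition."""
        rel = self.table["category"].to_numpy() == self.relevant_category
        return np.where(rel, "relevant", "irrelevant")

    def onsets(self) -> np.ndarray:
        return self.table["onset"].to_numpy(dtype=float)

    def validate(self, cfg: SimConfig) -> None:
        t = self.table
        onsets = self.onsets()
        if not np.all(np.diff(onsets) > 0):
            raise InvalidArgumentError("onsets must be strictly increasing")
        gaps = np.diff(onsets)
        if not np.all(np.isin(gaps, cfg.iti_choices_s)):
            raise InvalidArgumentError("onset gaps outside iti_choices_s")
        n_match = int((t["match"] == "match").sum())
        if n_match != cfg.matches_per_run:
            raise InvalidArgumentError(f"expected {cfg.matches_per_run} matches, got {n_match}")
        match_cats = t.loc[t["match"] == "match", "category"]
        if not (match_cats == self.relevant_category).all():
            raise InvalidArgumentError("matches must all lie in the relevant category")

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, condition: str, run_id: str, tms_condition: str
    ) -> "EventTable":
        table = pd.read_csv(path, sep="\t")
        table["correct"] = table["correct"].astype(bool)
        return cls(table=table, condition=condition, run_id=run_id, tms_condition=tms_condition)


@dataclass
class Volume4D:
    """A 4-D BOLD grid (X, Y, Z, T) with acquisition geometry."""

    data: np.ndarray
    voxel_size_mm: float
    tr_s: float
    t0_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ShapeError(f"Volume4D requires 4-D data, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("Volume4D data must be finite")

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def vol_times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_vols) * self.tr_s

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms((self.voxel_size_mm,) * 3 + (self.tr_s,))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, t0_s: float = 0.0) -> "Volume4D":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        return cls(
            data=np.asarray(img.dataobj, dtype=float),
            voxel_size_mm=float(zooms[0]),
            tr_s=float(zooms[3]),
            t0_s=t0_s,
        )


@dataclass
class MotionParams:
    """Per-volume rigid-body motion traces (x, y, z, roll, pitch, yaw)."""

    data: np.ndarray  # (T, 6)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ShapeError(f"MotionParams must be (T, 6), got {self.data.shape}")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.data, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotionParams":
        return cls(pd.read_csv(path, sep="\t")[MOTION_COLUMNS].to_numpy(dtype=float))


# --------------------------------------------------------------------------
# Planted code maps
# --------------------------------------------------------------------------


def _expand_code(
    cfg: SimConfig, code: dict[str, float | np.ndarray], tag: int
) -> np.ndarray:
    """Full-grid signed amplitude map for one code (category or relevance).

    Scalar entries become random-sign patterns of constant magnitude; the
    signs are a deterministic function of the config seed alone, so the map
    is shared across subjects, runs and conditions.
    """
    amp = np.zeros(cfg.grid_dims)
    for rid, value in code.items():
        mask = cfg.regions[rid]
        n = int(mask.sum())
        if np.isscalar(value):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [int(cfg.seed), 7919, tag, zlib.crc32(rid.encode()) % (2**31)]
                )
            )
            signs = rng.choice([-1.0, 1.0], size=n)
            amp[mask] = float(value) * signs
        else:
            value = np.asarray(value, dtype=float)
            if value.shape == cfg.grid_dims:
                amp[mask] = value[mask]
            elif value.shape == (n,):
                amp[mask] = value
            else:
                raise ShapeError(
                    f"code pattern for {rid!r} has shape {value.shape}; expected "
                    f"({n},) or {cfg.grid_dims}"
                )
    return amp


def planted_maps(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(category map, relevance map): signed per-voxel amplitudes, full grid."""
    return _expand_code(cfg, cfg.category_code, 1), _expand_code(cfg, cfg.relevance_code, 2)


def disruption_map(cfg: SimConfig) -> np.ndarray:
    """Per-voxel multiplier applied to planted codes in the disrupted condition."""
    att = np.ones(cfg.grid_dims)
    for rid, f in cfg.disruption_factors.items():
        att[cfg.regions[rid]] = f
    return att


# --------------------------------------------------------------------------
# Run design
# --------------------------------------------------------------------------


def make_run_design(
    cfg: SimConfig,
    condition: str,
    rng: np.random.Generator,
    run_id: str = "run-01",
    tms_condition: str = CONTROL,
    p_correct: float = 0.9,
) -> EventTable:
    """Draw one run's pseudo-random trial sequence.

    Half the trials show the task-relevant category and half the irrelevant
    one; consecutive relevant stimuli are separated by at most
    ``cfg.max_intervening_irrelevant`` irrelevant images; exactly
    ``cfg.matches_per_run`` trials are one-back matches, necessarily within
    the relevant category.
    """
    if condition not in TASK_CONDITIONS:
        raise InvalidArgumentError(f"unknown task condition {condition!r}")
    n = cfg.trials_per_run
    n_rel = n // 2
    max_gap = cfg.max_intervening_irrelevant

    # relevant/irrelevant arrangement by rejection sampling
    base = np.array([True] * n_rel + [False] * (n - n_rel))
    for attempt in range(10_000):
        seq = rng.permutation(base)
        rel_pos = np.flatnonzero(seq)
        if np.all(np.diff(rel_pos) - 1 <= max_gap):
            break
    else:
        raise DesignInfeasibleError(
            "could not place relevant trials with the intervening-irrelevant constraint"
        )

    relevant_cat = FACE if condition == REMEMBER_FACES else SCENE
    other_cat = SCENE if relevant_cat == FACE else FACE
    categories = np.where(seq, relevant_cat, other_cat)

    # one-back matches: any relevant trial except the first may repeat its
    # relevant predecessor
    candidates = rel_pos[1:]
    if cfg.matches_per_run > candidates.size:
        raise DesignInfeasibleError("matches_per_run too large for this run length")
    match_pos = rng.choice(candidates, size=cfg.matches_per_run, replace=False)
    match = np.full(n, "nonmatch", dtype=object)
    match[np.sort(match_pos)] = "match"

    gaps = rng.choice(cfg.iti_choices_s, size=n - 1)
    onsets = cfg.pre_task_rest_s + np.concatenate([[0.0], np.cumsum(gaps)])
    correct = rng.random(n) < p_correct

    table = pd.DataFrame(
        {
            "onset": onsets,
            "duration": cfg.stim_duration_s,
            "category": categories,
            "match": match,
            "correct": correct,
        }
    )
    ev = EventTable(table=table, condition=condition, run_id=run_id, tms_condition=tms_condition)
    ev.validate(cfg)
    return ev


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------


def simulate_run(
    cfg: SimConfig,
    events: EventTable,
    rng: np.random.Generator,
    relevance_scale: float = 1.0,
    maps: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[Volume4D, MotionParams]:
    """Generate one run's 4-D BOLD volume and its motion traces.

    The voxel time series is the sum of HRF-convolved trial responses scaled
    by the planted code amplitudes (face = +1 / scene = -1 for the category
    pattern, relevant = +1 / irrelevant = -1 for the relevance pattern, the
    latter scaled per subject by ``relevance_scale``), attenuated by the
    disruption map in the disrupted condition, plus polynomial drift, a random
    linear combination of the returned motion traces, and i.i.d. Gaussian
    noise.
    """
    cat_map, rel_map = planted_maps(cfg) if maps is None else maps
    att = disruption_map(cfg) if events.tms_condition == DISRUPTED else np.ones(cfg.grid_dims)

    onsets = events.onsets()
    duration_s = onsets[-1] + cfg.post_task_rest_s
    T = int(np.ceil(duration_s / cfg.tr_s))
    nvox = int(np.prod(cfg.grid_dims))

    categories = events.table["category"].to_numpy()
    face_on = onsets[categories == FACE]
    scene_on = onsets[categories == SCENE]
    face_reg = hrf.stimulus_regressor(face_on, cfg.stim_duration_s, T, cfg.tr_s)
    scene_reg = hrf.stimulus_regressor(scene_on, cfg.stim_duration_s, T, cfg.tr_s)

    rel_sign_face = 1.0 if events.condition == REMEMBER_FACES else -1.0
    amp_face = att * (cat_map + relevance_scale * rel_sign_face * rel_map)
    amp_scene = att * (-cat_map - relevance_scale * rel_sign_face * rel_map)

    signal = np.outer(face_reg, amp_face.ravel()) + np.outer(scene_reg, amp_scene.ravel())

    # polynomial drift, orders 0..drift_order on normalized time
    u = np.linspace(-1.0, 1.0, T)
    powers = np.stack([u**k for k in range(cfg.drift_order + 1)], axis=1)
    drift_coeffs = rng.uniform(-cfg.drift_coeffs_range, cfg.drift_coeffs_range,
                               size=(cfg.drift_order + 1, nvox))
    drift = powers @ drift_coeffs

    # slow motion traces coupled linearly into each voxel
    traces = np.cumsum(rng.normal(0.0, cfg.motion_sd, size=(T, 6)), axis=0)
    coupling = rng.normal(0.0, cfg.motion_coupling, size=(6, nvox))
    motion_term = traces @ coupling

    noise = rng.normal(0.0, cfg.noise_sd, size=(T, nvox)) if cfg.noise_sd > 0 else 0.0

    data = (signal + drift + motion_term + noise).T.reshape(cfg.grid_dims + (T,))
    vol = Volume4D(data=data, voxel_size_mm=cfg.voxel_size_mm, tr_s=cfg.tr_s)
    return vol, MotionParams(traces)


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------


@dataclass
class SimulatedRun:
    events: EventTable
    volume: Volume4D
    motion: MotionParams
    seed: list[int]


@dataclass
class Cohort:
    """In-memory simulated cohort: runs, behavior table and planted truth."""

    cfg: SimConfig
    runs: dict[str, dict[str, list[SimulatedRun]]]  # subject -> tms -> runs
    behavior: pd.DataFrame  # subject, tms_condition, accuracy
    relevance_scales: dict[str, float]
    category_map: np.ndarray
    relevance_map: np.ndarray

    @property
    def subjects(self) -> list[str]:
        return list(self.runs.keys())


def _child_rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) for k in key]))


def simulate_cohort_arrays(cfg: SimConfig) -> Cohort:
    """Simulate the full cohort in memory (no file I/O).

    Every artifact is a deterministic function of the config, including its
    seed: per-(subject, condition, run) child seeds are derived from
    ``cfg.seed`` with fixed integer keys.
    """
    cat_map, rel_map = planted_maps(cfg)
    behavior_rows = []
    runs: dict[str, dict[str, list[SimulatedRun]]] = {}
    scales: dict[str, float] = {}
    bm = cfg.behavior
    designated_amp = 0.0
    if bm.region in cfg.regions:
        designated_amp = float(np.abs(rel_map[cfg.regions[bm.region]]).mean())

    for s in range(cfg.n_subjects):
        subject = f"sub-{s + 1:02d}"
        srng = _child_rng(cfg.seed, 1000 + s)
        scale = max(0.1, 1.0 + srng.normal(0.0, cfg.subject_amp_sd))
        scales[subject] = scale
        base_acc = bm.baseline + bm.slope * scale * designated_amp
        runs[subject] = {}
        for c, tms in enumerate(TMS_CONDITIONS):
            acc = base_acc + srng.normal(0.0, bm.noise_sd)
            if tms == DISRUPTED:
                acc -= bm.disrupted_decrement
            acc = float(np.clip(acc, 0.0, 1.0))
            behavior_rows.append({"subject": subject, "tms_condition": tms, "accuracy": acc})
            run_list = []
            r = 0
            for condition in TASK_CONDITIONS:
                for _ in range(cfg.runs_per_condition):
                    seed_key = [cfg.seed, 2, s, c, r]
                    rng = _child_rng(*seed_key)
                    run_id = f"run-{r + 1:02d}"
                    ev = make_run_design(
                        cfg, condition, rng, run_id=run_id, tms_condition=tms, p_correct=acc
                    )
                    vol, motion = simulate_run(
                        cfg, ev, rng, relevance_scale=scale, maps=(cat_map, rel_map)
                    )
                    run_list.append(SimulatedRun(ev, vol, motion, seed_key))
                    r += 1
            runs[subject][tms] = run_list

    behavior = pd.DataFrame(behavior_rows)
    return Cohort(cfg, runs, behavior, scales, cat_map, rel_map)


def _config_manifest(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["regions"] = sorted(cfg.regions.keys())
    d["behavior"] = dataclasses.asdict(cfg.behavior)
    for key in ("category_code", "relevance_code"):
        d[key] = {
            k: (v if np.isscalar(v) else np.asarray(v).tolist()) for k, v in d[key].items()
        }
    return d


def simulate_cohort(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort and write it as a dataset directory.

    Layout: ``sub-XX/<tms>/run-YY_{bold.nii.gz,events.tsv,motion.tsv}``,
    region and brain masks under ``masks/``, ``behavior.tsv``, and a
    ``manifest.json`` recording config, seeds and the file index.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort_arrays(cfg)

    import nibabel as nib

    masks_dir = out / "masks"
    masks_dir.mkdir(exist_ok=True)
    affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
    for rid, mask in cfg.regions.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(masks_dir / f"{rid}.nii.gz"))
    brain = np.ones(cfg.grid_dims, dtype=np.uint8)
    nib.save(nib.Nifti1Image(brain, affine), str(masks_dir / "brain.nii.gz"))

    index = []
    for subject in cohort.subjects:
        for tms in TMS_CONDITIONS:
            run_dir = out / subject / tms
            run_dir.mkdir(parents=True, exist_ok=True)
            for run in cohort.runs[subject][tms]:
                stem = run.events.run_id
                run.volume.to_nifti(run_dir / f"{stem}_bold.nii.gz")
                run.events.to_tsv(run_dir / f"{stem}_events.tsv")
                run.motion.to_tsv(run_dir / f"{stem}_motion.tsv")
                index.append(
                    {
                        "subject": subject,
                        "tms_condition": tms,
                        "run_id": stem,
                        "condition": run.events.condition,
                        "seed": run.seed,
                        "bold": f"{subject}/{tms}/{stem}_bold.nii.gz",
                        "events": f"{subject}/{tms}/{stem}_events.tsv",
                        "motion": f"{subject}/{tms}/{stem}_motion.tsv",
                    }
                )
    cohort.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)

    manifest = {
        "config": _config_manifest(cfg),
        "regions": sorted(cfg.regions.keys()),
        "relevance_scales": cohort.relevance_scales,
        "behavior_file": "behavior.tsv",
        "runs": index,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_cohort(dataset_dir: str | Path) -> tuple[dict, pd.DataFrame]:
    """Read a dataset directory's manifest and behavior table."""
    root = Path(dataset_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    behavior = pd.read_csv(root / "behavior.tsv", sep="\t")
    return manifest, behavior


def config_from_manifest(manifest: dict, dataset_dir: str | Path) -> SimConfig:
    """Reconstruct a SimConfig from a dataset manifest plus its mask files."""
    import nibabel as nib

    root = Path(dataset_dir)
    raw = dict(manifest["config"])
    regions = {}
    for rid in raw.pop("regions"):
        img = nib.load(str(root / "masks" / f"{rid}.nii.gz"))
        regions[rid] = np.asarray(img.dataobj).astype(bool)
    raw["regions"] = regions
    raw["grid_dims"] = tuple(raw["grid_dims"])
    raw["iti_choices_s"] = tuple(raw["iti_choices_s"])
    raw["behavior"] = BehaviorModel(**raw["behavior"])
    for key in ("category_code", "relevance_code"):
        raw[key] = {
            k: (v if np.isscalar(v) else np.asarray(v)) for k, v in raw[key].items()
        }
    return SimConfig(**raw)


def load_cohort_runs(dataset_dir: str | Path) -> Cohort:
    """Reconstruct an in-memory Cohort from a dataset directory on disk."""
    root = Path(dataset_dir)
    manifest, behavior = load_cohort(root)
    cfg = config_from_manifest(manifest, root)
    cat_map, rel_map = planted_maps(cfg)
    runs: dict[str, dict[str, list[SimulatedRun]]] = {}
    for rec in manifest["runs"]:
        subject, tms = rec["subject"], rec["tms_condition"]
        ev = EventTable.from_tsv(
            root / rec["events"], rec["condition"], rec["run_id"], tms
        )
        vol = Volume4D.from_nifti(root / rec["bold"])
        motion = MotionParams.from_tsv(root / rec["motion"])
        runs.setdefault(subject, {}).setdefault(tms, []).append(
            SimulatedRun(ev, vol, motion, rec["seed"])
        )
    scales = {k: float(v) for k, v in manifest.get("relevance_scales", {}).items()}
    return Cohort(cfg, runs, behavior, scales, cat_map, rel_map)
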