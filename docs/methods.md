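# Methods

This note documents the models, numerical choices and limitations of the
package in one place. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Synthetic cohort model

The generator emulates a two-session within-subject disruption experiment.
Per subject and disruption condition (`control`, `disrupted`) it produces
`runs_per_condition` (default 5) runs of each task condition
("Remember Faces" / "Remember Scenes"), each with `trials_per_run = 20`
trials of 600 ms, onset gaps drawn uniformly from {3, 5, 7} s, TR = 1 s.
Trials are half faces, half scenes (fixed 10/10: balanced classes are a
precondition for unbiased decoding); consecutive task-relevant stimuli are
separated by 0–3 irrelevant ones (rejection sampling); exactly
`matches_per_run = 4` one-back matches fall on relevant trials that have a
relevant predecessor. Onsets sit on the TR grid starting 4 s into the run;
the run ends 12 s after the last onset (≈ 107–115 s), so the run length
adapts to the jitter rather than truncating the design.

**Forward model.** A voxel's time series is

```
y(t) = Σ_trials r(t − onset) · a_v(trial) + drift + motion coupling + ε
```

where `r` is a 600 ms boxcar convolved with the canonical double-gamma HRF
(response peak 6 s, undershoot peak 16 s, unit dispersions, undershoot ratio
1/6), normalized so one isolated trial peaks at 1 — hence planted amplitudes
are in units of peak BOLD excursion. The per-trial amplitude is

```
a_v = att_v · (cat_v · s_cat + scale_subj · rel_v · s_rel)
```

with `s_cat = +1/−1` for face/scene, `s_rel = +1/−1` for relevant/irrelevant,
`cat_v`, `rel_v` signed voxel patterns confined to designated regions, and
`att_v` the disruption attenuation (1 everywhere in the control condition;
per-region factors in [0, 1] in the disrupted condition). Scalar code
amplitudes expand to random-sign patterns of constant magnitude, a choice
that makes the planted map recoverable up to scale after per-voxel temporal
z-scoring (a z-scored noise-free voxel keeps only its sign). Disruption
attenuates *all* planted code content in a region; with the default layout
(category and relevance codes in disjoint regions) this is equivalent to
attenuating each code separately.

Nuisance terms: polynomial drift of orders 0–3 with coefficients uniform in
±`drift_coeffs_range` (default 0.5); six slow motion traces (random walks of
step sd `motion_sd` = 0.05) coupled into each voxel with N(0, 0.5²) weights;
i.i.d. Gaussian noise of sd `noise_sd` = 1.

**Calibration.** Default amplitudes are category 0.15 and relevance 0.20,
calibrated once so a single subject's 27-voxel ROI decodes each code at
roughly 70 %; the default attenuations (category ×0.8, relevance ×0.5) then
produce a small category effect and a large relevance effect, mirroring the
qualitative pattern such experiments report. Behavioral accuracy is
`baseline + slope · (subject relevance amplitude in the designated region)`
plus N(0, 0.02) noise, minus 0.028 in the disrupted condition, clipped to
[0, 1]; with baseline 0.83 and slope 0.5 the cohort means land near 93 %
(control) and 90 % (disrupted). Per-subject relevance amplitude scales are
`max(0.1, 1 + N(0, 0.25))`, which both drives the behavior link and gives
subjects realistic heterogeneity in code strength.

**Determinism.** Every artifact is a function of the config including its
seed; per-(subject, condition, run) generators derive from fixed integer key
sequences, and region sign patterns are seeded by the config seed and a CRC
of the region name, so datasets, manifests and reports are bit-reproducible.

**What the simulation does not emulate.** No spatial autocorrelation of the
noise, no physiological confounds or scanner artifacts, no slice timing, no
registration error, no hemodynamic variability across regions or subjects,
and both codes share their stimulus time course (they decouple only through
the task-condition structure). Passing tests therefore demonstrate the
correctness and calibration of the *statistics* under a known generative
model, not robustness to real fMRI noise structure.

## Preprocessing

Per run, an OLS GLM with one HRF-convolved regressor per stimulus-category ×
task-condition combination present in the run (2 for the simulated designs),
the six motion traces, and a polynomial baseline. The quintic baseline is
implemented as six columns (orders 0–5, QR-orthonormalized on the sample
grid): a lone fifth-order term could model neither the mean nor low-order
drift. The fitted motion + polynomial component is subtracted; the
stimulus-fitted component is deliberately retained, so the *output* is not
orthogonal to the nuisance columns — the orthogonality contract applies to
the full-model residual, reconstructible from the stored betas
(`meta["glm_beta"]`). Runs are then z-scored per voxel over time (sample sd,
ddof 1; voxels with sd < 1e−12 are zeroed and flagged).

Trial patterns take the single volume whose acquisition start time lies in
`[onset + low, onset + high)` — windows (5, 6) s for the category code and
(6, 7) s for relevance; with TR 1 s and integer onsets the volume is unique,
and any window covering 0 or ≥ 2 volumes raises an error rather than
guessing.

## Classifiers

*ROI*: binary logistic regression with L2 penalty λ (default 1.0, fixed — no
nested tuning, which keeps permutation nulls exchangeable) on the weights
but not the intercept, solved by damped-free Newton iterations to gradient
norm 1e−8; predictions threshold the class probability at 0.5 with exact
ties going to the lexicographically smaller label. A batched solver fits
hundreds of permuted label vectors against a shared design at once (the
Hessians are batched 29×29 solves), which is what makes the permutation
studies cheap.

*Searchlight*: Gaussian Naive Bayes with class means and pooled within-class
variance (per-voxel floor 1e−6; per-class variance available as an option —
pooling is the default because ≤ 100 training trials per class make
per-class variances unstable). Cubes of edge 3 or 5 are clipped at volume
and mask borders; a center is valid only if at least half of the cube's
voxels are in the mask. The batched implementation computes class means as
label-indicator matrix products and cube sums by separable uniform filters;
it is verified voxel-for-voxel against a per-center brute-force GNB.

## Inference

Permutations shuffle labels within run (runs are the exchangeability blocks
given per-run z-scoring); the identity permutation is excluded; the same
pre-generated sets are reused across ROIs and across disruption conditions,
making condition differences matched permutation-by-permutation. Empirical
p-values use the plain fraction `#(null > observed)/n` (a `(k+1)/(n+1)`
variant is available); Bonferroni families are the number of ROI × condition
(above-chance) or ROI (difference) tests in the invocation and are logged.

Searchlight group inference follows the bootstrap scheme: per subject,
`n_null` null difference maps (same permutation index applied in both
conditions), smoothed exactly like the true maps (unequal smoothness would
bias the null); `n_boot` group maps each average one uniformly drawn null
map per subject; a voxel passes if the true group value strictly exceeds
the fraction `1 − voxel_alpha` of its bootstrap values (per-voxel, not
pooled); null group maps are thresholded by the same per-voxel rule, the
maximum face-connected (6-neighborhood) cluster size of each is recorded,
and an observed cluster survives if strictly larger than `1 − cluster_alpha`
of the null maxima. Defaults mirror the full-scale procedure
(n_perm = 1000, n_null = 100, n_boot = 100 000, both alphas 0.005); all are
config-scalable, and the shipped tests and scripts use desk-scale values
(n_perm 99–500, n_null 20, n_boot 2000–5000, grids 12×12×8 and smaller) so
the whole suite runs in minutes on one CPU.

Functional ROIs: one-sample t (one-sided, greater) of subject accuracy maps
against 0.5 per all-subject-valid voxel, Benjamini–Hochberg over valid
voxels at q (default 1e−4); zero-variance voxels are excluded with a
warning.

Spearman correlation uses average ranks and, for n ≤ 9, the exact two-sided
permutation distribution of the rank correlation (all n! assignments);
larger n uses the t approximation. The median-split Welch test sorts by
behavioral decrement (stable sort, so ties fall to the most-impaired half;
odd n drops the median subject) and reports t with Welch–Satterthwaite
fractional degrees of freedom, two-sided.

## Known limitations

* **Finite-null anticonservatism of the bootstrap cluster correction.** With
  `n_null` maps per subject, every bootstrap group map is a mean over the
  same per-subject atoms while the observed group map is one fresh draw per
  subject, so the voxelwise exceedance rate of a truly null observed map is
  inflated above `voxel_alpha` (Monte Carlo with 8 subjects: ≈ 0.0093
  instead of 0.005 at n_null = 20, still ≈ 0.0078 at n_null = 100), and the
  cluster-size null — built from maps that pass at exactly `voxel_alpha` by
  rank construction — inherits the leniency. On fully null simulated
  cohorts at n_null = 20 the realized family-wise error is a few percent
  rather than 0.5 %. Users wanting tighter control should raise `n_null`
  substantially or treat surviving clusters near the size threshold with
  caution.
* The searchlight accuracy map of a compact source is intrinsically dilated
  by the cube radius (any center within 2 voxels of a 3³ source holds the
  whole source in its 5³ cube), so recovered clusters localize to the
  dilated support of a planted region, not its exact voxels.
* ROI logistic regression uses a fixed λ; no feature selection, no
  alternative classifiers, no temporal decoding beyond the single lag
  volume, no parametric (random-field) correction, and no real-data
  registration or atlas handling — masks are taken as given.
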