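# Methods

This note documents the models, numerical choices and limitations behind
`strata-ifc`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the acceptance script, not
asserted from elsewhere.

## Study design being modelled

Two groups: healthy controls measured once (M1) and patients measured before
(M1) and after (M2) roughly six weeks of stimulant treatment. Clinical state
is summarized by eight features — DSM-IV criterion A1 and A2 symptom counts
from a structured interview, and six CAARS DSM-oriented subscale scores
(self- and observer-rated inattention, hyperactivity/impulsivity, and
total). Imaging is resting-state fMRI: 180 volumes at TR = 2.4 s, analyzed
after standard spatial preprocessing (which is upstream of this package; the
pipeline ingests preprocessed 4D arrays or ROI × time matrices).

## Clinical statistics (`clinstats`)

* Two-sample comparisons use the pooled-variance Student t, not Welch. A
  published df of n₁+n₂−2 (= 101 for 53 vs 50) identifies the pooled test;
  Cohen's d uses the pooled SD, so sign(t) = sign(d) and d is invariant
  under common affine rescaling. Sample SDs use the n−1 denominator
  throughout, the convention of clinical reporting.
* The 2×2 chi-square is Pearson's without continuity correction — the
  corrected statistic would not reproduce published values computed without
  it.
* `screening_alpha` solves for the significance level at which the t-test
  attains a requested power for a given effect size, via the noncentral t
  with ncp = d√(n₁n₂/(n₁+n₂)). One-tailed is the default because the screen
  tests hyper- and hypoconnectivity as separate directed contrasts;
  `tails="two"` solves the two-tailed problem by bisection, counting the
  (tiny) wrong-tail rejection mass exactly. For n = 53/50, d = 0.8, power
  0.8 the one-tailed solution is α ≈ 0.00091, consistent with a p < 0.001
  screen.
* Pooled z-normalization is estimated on the M1 sample (patients and
  controls together) and *frozen*: M2 data are transformed with the stored
  M1 means/SDs, never refit, so follow-up scores are expressed on the
  baseline scale. A constant feature is an error, not silently passed.

## Responder classification (`respclass`)

Five members, fixed hyperparameters, no tuning and no probability
calibration — votes are hard labels:

| member | backing | settings |
|---|---|---|
| svm_linear | sklearn SVC | C = 1, linear kernel, offset 0 |
| svm_gaussian | sklearn SVC | C = 1, kernel exp(−‖x−y‖²), i.e. scale 1 on z-scored features |
| knn_euclidean / knn_cosine / knn_chisquare | direct implementation | k = 1, exhaustive search, equal weights |

The 1-NN members are implemented directly (on `scipy.spatial.distance.cdist`
plus a vectorized chi-square distance) because two contract details are not
guaranteed by library KNN classifiers: distance ties break toward the
smallest training-row index (`np.argmin` semantics), and the chi-square
distance must operate on signed z-scores. The classical chi-square distance
Σ(xⱼ−yⱼ)²/(xⱼ+yⱼ) assumes nonnegative inputs; we use
Σ(xⱼ−yⱼ)²/(|xⱼ|+|yⱼ|+ε) with ε = 1e−8, which preserves the classical form
on nonnegative data and stays defined and nonnegative everywhere. The
original variant used on z-scored data in the source analysis environment is
not documented anywhere we could check; this is a documented choice, and the
ensemble's behaviour is insensitive to it on separable data (the tests
exercise this).

An SVM decision value of exactly 0 votes "patient" — conservative toward
non-response, and a measure-zero event. Five members force a strict
majority; ≥ 3 "control" votes ⇒ Responder.

## Connectivity (`ifc`)

Order fixed: confound regression → linear detrend → band-pass.

* **Regression** is per-voxel OLS against [intercept, confounds]; residuals
  are exactly orthogonal to every confound column and the step is
  idempotent. Rank-deficient confound matrices have collinear columns
  dropped with a warning. Nuisance sources follow the aCompCor convention:
  principal components of noise-tissue signal (defaults 10 white-matter + 5
  CSF), motion regressors (12), and one-hot outlier-scan indicators
  (scrubbing by regression). Components come from an SVD of the
  row-centered voxel × time submatrix; they are returned unit-norm and
  orthogonal. Outlier *detection* (frame-wise displacement etc.) needs
  realignment parameters this package does not compute; indicators are
  accepted as upstream inputs.
* **Band-pass** (default 0.008–0.09 Hz) is a hard mask of the real-FFT
  bins: deterministic, exactly the stated band, with brick-wall roll-off.
  This is a deliberate simplification relative to simultaneous
  regression-plus-filtering implementations in established toolboxes; a
  consequence is that the filtered output is orthogonal to *filtered*
  confounds rather than bin-exactly to raw ones. At TR 2.4 s / 180 volumes
  the measured response is ≥ 99% retention at 0.05 Hz and ≤ 1% leakage at
  0.15 Hz.
* **Mapping**: r = Pearson correlation of the seed-mask mean time course
  with each voxel, z = atanh(r) with r clamped to ±(1−1e−7) (finite maps;
  clamped and zero-variance voxels are flagged and excluded from inference
  masks by the caller). The clamp makes the degenerate self-correlation
  z ≈ 8.41 — far outside any attainable genuine value.

## Group inference (`groupinfer`)

* **Screening** is a one-tailed pooled t per voxel at unadjusted α
  (deliberately uncorrected — it only defines the search volume for the
  corrected stage), plus an extent threshold (default k = 5) under
  18-connectivity, the convention of the software family this mirrors.
  Hyper- and hypo-masks are disjoint by construction.
* **Conjunction**. The 2×2 Group×Time factorial with Time within subject is
  re-expressed through change scores Δᵢ = z(M2) − z(M1), signed toward
  normalization (positive = toward controls in a hypo mask, reversed in a
  hyper mask): interaction = two-sample t of Responder vs Non-Responder Δ;
  simple effect = one-sample t of Responder Δ. For this design the
  change-score tests are algebraically equivalent to the factorial
  contrasts, and they avoid a general GLM with subject blocks. The
  conjunction requires both, so t_conj = min(t_int, t_simple) and the
  uncorrected p is the max of the component p-values (conjunction null:
  both effects null).
* **FWE**. Default Bonferroni over the mask voxels (p_fwe = min(1, m·p)),
  which is monotone in mask size and exact at m = 1. Optionally a
  permutation max-T null: each of n_perm draws sign-flips every subject's Δ
  (enforcing the simple-effect null) *and* permutes subgroup labels
  (enforcing the interaction null), recomputes the min-t map, and records
  its maximum; p = (1 + #{maxT ≥ t})/(1 + n_perm). Random-field-theory
  correction is deliberately not implemented: smoothness estimation is
  unstable on toy grids, so published RFT-corrected p-values are not
  reproducible here — the framework's logic is, and that is what the tests
  verify.
* **Effect size** per cluster: d = t_int·√(1/n_R + 1/n_NR) at the peak
  voxel. How the corresponding published values were derived is not
  documented; this definition is our documented choice, not a replication.
* Peak "z_value" is the normal-quantile equivalent of the uncorrected
  conjunction p at the peak.

## Synthetic cohort (`synthcohort`)

The generator's defaults are the study conditions: 50 controls, 53 patients,
36 Responders / 17 Non-Responders; per-feature baseline means/SDs follow
the published group characteristics (e.g. self-rated inattention 19.11 ± 4.18
in patients vs 5.24 ± 3.41 in controls). M2 subgroup means are
mean_pat + ρ·(mean_hc − mean_pat) with reversion ρ = 1.0 for Responders and
0.2 for Non-Responders — the published M2 summaries appear only in an
appendix we do not have, so these are free parameters chosen to encode
"Responders revert to near-normal, Non-Responders improve only mildly";
patient SDs are retained at M2. Features default to independent normals; an
optional common-factor correlation is available because CAARS subscales
correlate in reality (default 0 for test transparency).

Time series: seed voxels are w_s·L + σ√(1−w_s²)·ε and effect voxels
w_e·L + σ√(1−w_e²)·η for a shared white latent L, independent white noise,
seed loading w_s = 0.8 and noise scale σ (default 1, at which the target
calibration is exact). Averaging the m seed voxels gives
corr(seed mean, L) = w_s/√(w_s² + (1−w_s²)/m), so w_e is solved in closed
form from the group/timepoint target r — controls 0.5, patients 0.1 at
baseline, Responders back to 0.5 at M2, Non-Responders unchanged.
Background voxels are white noise plus an optional linear drift. Defaults:
12×12×8 voxel grid (large enough for extent thresholds, small enough for
seconds-scale runs), 180 volumes, TR 2.4 s, an 8-voxel seed block and a
30-voxel effect slab.

What the generator does **not** model: hemodynamic autocorrelation, head
motion, spatial smoothness/autocorrelation, within-subject M1→M2
correlation of clinical scores, multi-site effects. Passing tests therefore
demonstrate the correctness and calibration of the *analysis stream* under
its own assumptions (independent Gaussian noise, white signals), not
robustness to realistic fMRI artefacts. In particular the null calibration
result inherits the independence of voxel noise; on spatially smooth data
Bonferroni over voxels would be more conservative, not less.

## Problem sizes in the validation suite

Clinical-scale checks run at the study sizes (53/50). Planted-effect
recovery runs the full pipeline (including classification and denoising) on
the default 12×12×8 grid, 180 volumes, 20 replicates; null calibration of
the conjunction FWE uses 100 replicates on a reduced 10×10×6 grid with the
denoise stage skipped (the generated series contain no confounds or trends,
and the property under test belongs to the inference stage); the Monte-Carlo
power cross-check uses 10,000 replicates. These sizes were chosen to give
stable pass/fail behaviour at seconds-to-minutes runtimes.

## Known limitations

* Published peak coordinates/p-values from the motivating study are not
  reproducible without its (non-shareable) raw data; the package validates
  the framework on synthetic cohorts instead.
* The atlas-scale screen (hundreds of seeds) is supported only in the sense
  that the per-seed operations compose; no atlas ships with the package and
  no multi-seed correction beyond the documented screening logic is applied.
* `screening_alpha` assumes normal within-group data (exact noncentral-t
  power); it is a design calculation, not a robust test.
* The permutation max-T scheme enforces both component nulls
  simultaneously; milder composite nulls (only one component null true)
  make the test conservative, which the null-calibration test reflects.
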