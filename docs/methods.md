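# Methods

This note records what repsim computes, the conventions it fixes where the
field allows several, and what its synthetic-data tests do and do not show.

## Data model

All analyses take plain NumPy arrays with a strict axis convention,
enforced by `NeuroArray`: behavior `[condition, subject, trial]`, EEG-like
`[condition, subject, trial, channel, time]`, fMRI-like
`[condition, subject, x, y, z]`. Arrays in the wrong order are rejected,
never transposed silently — a transposed array is usually a bug upstream,
and guessing the intended order would hide it.

## RDM computation

The RDM entry for conditions *i, j* is `1 − similarity(d_i, d_j)`
(correlation distance) or a metric distance between the pattern vectors.
Fixed conventions:

- **Trial handling.** Trials are averaged within condition before any
  distance is computed. For behavioral data the per-condition trial vector
  itself is the pattern, so trial counts must agree across conditions
  (NaN-padded ragged arrays are rejected rather than imputed).
- **Correlation distance** is kept on its natural `1 − r ∈ [0, 2]` scale,
  not rescaled to [0, 1]. A zero-variance pattern makes Pearson r
  undefined and raises `ZeroVarianceError` naming the condition — except
  inside a searchlight, where one degenerate unit becomes a missing
  (all-NaN) RDM instead of aborting a whole-brain run.
- **Mahalanobis distance.** The feature covariance is estimated from the
  condition patterns with Ledoit–Wolf analytic shrinkage toward the scaled
  identity, then pseudo-inverted. With typical RSA geometry (few
  conditions, many features) the sample covariance is singular; shrinkage
  keeps the distance defined and stable. Cross-validated (crossnobis)
  distances are out of scope.
- **Voxel order.** Volumetric patterns are flattened x-fastest, then y,
  then z. The order only needs to be fixed and documented — all statistics
  used here are permutation-invariant over features — but it is relied on
  by the tests.
- **Windows.** Time windows are half-open `[start, start + time_win)` with
  `⌊(n_times − time_win)/time_step⌋ + 1` windows, the same arithmetic as
  the searchlight stride formula.
- **Missing data.** NaN voxels are dropped from every condition's ROI
  pattern (so patterns stay comparable); a searchlight unit containing any
  non-finite voxel yields a missing RDM marker. Nothing is imputed.

## Comparing RDMs

Comparison operates on the strictly-upper-triangle vectors (diagonal
excluded, one half only — shared diagonal zeros would otherwise inflate
the similarity). Five measures: Spearman (default — rank-based, robust to
monotone distortions of the dissimilarity scale, the common choice in the
RSA literature), Pearson, Kendall's τ-b, cosine, Euclidean.

**Permutation test.** The default null permutes the condition labels of
one RDM (rows and columns jointly) and re-vectorizes — the exchangeability
structure of a dissimilarity matrix lives on conditions, not on matrix
entries. Entry-wise shuffling of the vectorized RDM is available as
`scheme="entries"` for compatibility with tools that shuffle values
directly; the two nulls differ and the label scheme is the documented
default. The test is one-sided toward similarity (larger correlation,
smaller Euclidean distance). When the permutation group is small
(`n! ≤ n_iter` relabelings, or all `2^n` sign patterns at the group
level), the null is enumerated exhaustively and the p-value is exact;
otherwise the add-one Monte Carlo estimate `(1 + #{null ≥ obs})/(1 +
n_iter)` is used, which can never return 0. Default `n_iter` is 5000.
All stochastic operations take an explicit seed (default fixed at
12345) and are pure functions of their arguments.

`one_step_compare` is implemented literally as the composition of the RDM
front-ends with `broadcast_compare`, so the one-step and two-step routes
are identical by construction; the test suite still asserts elementwise
equality. Large maps without permutation go through a vectorized
rank-correlation pass that is numerically identical to the per-pair SciPy
route (asserted to 1e-12).

## NPS, STPS, ISC

- **NPS** correlates the two conditions' *trial-averaged* patterns (not
  the average of single-trial correlations): averaging first suppresses
  trial noise in both operands symmetrically and matches how the RDM
  pattern vectors are formed, making NPS exactly `1 − D_12` of the
  correlation RDM on the same patterns.
- **STPS** takes trial-level data plus per-trial labels and returns, per
  label, the mean pairwise Pearson r between flattened space×time windows
  of same-label trials. A `within_minus_between` contrast subtracts the
  mean correlation of differing-label pairs.
- **ISC** is pairwise over all `n(n−1)/2` canonical subject pairs
  (`i < j`); a leave-one-out variant (each subject against the mean of the
  others) is available as `method="loo"`. p-values are the parametric
  two-sided Pearson p.

## Group statistics

Per map index, subjects' r-values are tested against zero with a
one-sample t (df = n_subjects − 1), one-sided toward positive similarity
by default (`tail="two-sided"` available). The permutation alternative
sign-flips subject values — valid when the null distribution of each
subject's statistic is symmetric about zero, which holds for correlations
of independent RDMs — and flips at the level of subject-level statistics,
not within-subject data. No Fisher z-transform is applied by default
(`fisher_z=True` enables it); for a test of location against zero the
transform changes little and leaving r untransformed keeps the tested
quantity the one users see in maps. Indices with zero across-subject
variance or any NaN give `(NaN, NaN)` and leave the correction family.

Multiple comparisons: Benjamini–Hochberg FDR or Bonferroni FWE
(statsmodels implementations) over the family of all non-NaN indices in
the map — the whole map, not per slice.

## Volumetric export

Searchlight unit grids are projected back to voxels by averaging every
kernel that covers the voxel; non-finite (missing) units drop out of the
average, and voxels covered by no unit are 0 with a coverage flag. Export
order is: correction of the voxel p family → thresholding (survive iff
`p < p_threshold`, strictly, and `|value| ≥` the value threshold if given)
→ optional Gaussian smoothing (nilearn, FWHM in mm) of the value volume
only. Filtered voxels are written as 0 — the conventional sentinel,
indistinguishable from a genuine 0; `sentinel=nan` is available when that
matters. Files are 32-bit float NIfTI-1 with the given affine in both
qform and sform.

## Synthetic data

`PlantedDesign` fixes the study conditions: per-condition templates drawn
once from the seed (shared across subjects and trials, so both
within-subject and group-level recovery are testable), scaled by
`signal_effect`, restricted to `signal_support` (channels, or a voxel
blob), plus i.i.d. Gaussian noise of sd `noise_sd`. Templates and noise
come from separate seed streams, so `condition_templates` reproduces the
noiseless signal independently — that is how model RDMs for recovery
tests are built. With `signal_effect=0` the data are exchangeable across
conditions, giving an exact null for calibration tests.

The noise model is deliberately minimal: no autocorrelation, no
hemodynamic or ERP forward model, no inter-subject variability in the
templates. Passing calibration and recovery tests therefore shows the
*statistics* behave correctly under their assumptions, not that the
pipeline is robust to structured physiological noise. Template draws are
shape-dependent, so condition geometry is not coupled across modalities;
cross-modal recovery demos should build the model RDM from
`condition_templates` of the target modality.

## Problem sizes used in the acceptance script

The script runs 200 replicates per null-calibration check (n_iter = 1000),
20 replicates of blob recovery on a 12³ image (3³ kernel, stride 1, 6
subjects, 6 conditions, effect 5, noise 1), 50 oracle-agreement instances,
and one NIfTI round-trip — sizes chosen so the whole run completes in a
few seconds while keeping Monte-Carlo error on the calibration rates near
±0.015 (1 SE).

## Known limitations

- No classification-accuracy or DNN-layer RDMs; no crossnobis distances;
  no noise ceilings or bootstrapped model ranking.
- No cluster-based permutation correction or TFCE; the correction family
  is voxel/index-wise.
- ISC has no time-lagged variant and no ISFC.
- The CLI moves arrays as `.npy` files and does not read 4-D NIfTI time
  series; `read_fmri_nii` expects one 3-D volume per condition×subject.
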