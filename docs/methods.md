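# Methods

## Overview

`fcstrength` implements a whole-brain functional connectivity strength
(FCS) analysis of conversion from mild cognitive impairment (MCI) to
Alzheimer's disease (AD), built to run end to end on synthetic
resting-state cohorts.  The pipeline is: temporal preprocessing →
voxelwise FCS and seed-based connectivity → covariate-adjusted group
inference with Monte-Carlo cluster-extent correction → leave-one-out SVM
discrimination of MCI converters from nonconverters → a robustness suite
over correlation thresholds, motion covariates and global signal
regression.  Because no raw imaging data are available for this design,
the synthetic cohort generator is a first-class, tested component: it
defines the statistical conditions under which every downstream claim is
checked.

## Synthetic cohort model

Each subject's BOLD series on a regular grid (default 24×24×18 voxels at
3 mm isotropic, 150 frames at TR = 2 s) is

    y_v(t) = a_k · s_k(t) + c_g · g(t) + c_w · w(t) + c_c · c(t) + ε_v(t)

where voxel *v* belongs to network *k* (coupling weight `a_k`, zero for
off-network gray matter), `s_k`, `g`, `w`, `c` are independent
unit-variance latent signals band-limited to 0.01–0.08 Hz (white noise
FFT-masked to the analysis band, so realistic spectra survive
preprocessing), and ε is iid Gaussian with standard deviation `noise_sd`
(default 1).  With zero confounds the expected in-network pairwise
correlation is `a²/(a² + σ²)`, which is the closed form the generator
tests use.  White-matter and CSF compartments carry their own latent
signals at unit amplitude and leak into gray matter at the configured
amplitudes (defaults: global 0.5, WM 0.3, CSF 0.3), giving nuisance
regression and global signal regression (GSR) something real to remove.

Two disjoint cuboid networks are planted: `angular_like`
(posterior-superior, default-mode territory) and `occipital_like`
(posterior-inferior, visual territory), each spanning a quarter of every
grid dimension.  Group coupling defaults encode the graded deficit the
analysis is designed to detect — NC 1.0, MCI-nonconverter 0.8,
MCI-converter 0.55, AD 0.45 — with the converter weight the lowest among
the MCI subgroups.  No quantitative effect sizes are published for FCS
group differences, so the gap sizes are free generator parameters chosen
once to give a clearly graded but noise-limited signal; they are not
fitted to any result.

Demographics and cognitive scores (MMSE, MoCA, CDT, AVLT immediate /
delayed / recognition) are drawn from group-specific normal distributions
parameterized to the published per-group means and SDs of the clinical
cohort (25 AD / 31 MCI / 42 controls; 21 of the MCI converted within
roughly two years), clipped to instrument ranges.  Age and sex are drawn
independently of coupling by default; `age_coupling_slope` optionally
couples age to the planted deficit for covariate-adjustment experiments.
Head motion is a random walk (cumulative iid Gaussian steps, default
0.05 mm translation and 0.001 rad rotation steps), making framewise
displacement stationary.

All randomness flows from one spec seed: `SeedSequence(seed)` spawns one
child for the subject table and one per subject (ordered AD block, MCI
block with converters first, NC block); each subject child spawns BOLD
and GM-map streams.  Identical specs therefore yield bit-identical
cohorts.

## Preprocessing

Per voxel: linear detrend (least-squares line including intercept), then
an ideal FFT-mask band-pass keeping bins in [0.01, 0.08] Hz inclusive,
then least-squares residualization on an intercept plus nuisance
regressors — the six motion parameters, WM and CSF mean signals, and
(when GSR is on, the default) the mean signal over the gray-matter
analysis mask.  Confound series are extracted from the band-passed data
so regressors and data occupy the same band; regression after ideal
filtering is idempotent.  Rank-deficient nuisance designs are rejected
with the collinear columns named (QR with column pivoting).

Framewise displacement uses the sum-of-absolute-derivatives form,
`FD_i = Σ|Δtrans| + r·Σ|Δrot|` at an assumed 50 mm head radius, first
frame 0.  The group gray-matter mask includes a voxel iff the mean of all
subjects' GM probability maps is ≥ 0.2; the boundary is inclusive by
stated convention.

Spatial steps of real-data pipelines (slice timing, realignment,
segmentation-based normalization, smoothing of subject data) are out of
scope: synthetic data are born on a common grid, and Gaussian smoothing
appears only inside the null-field simulator of the cluster correction.

## Functional connectivity strength

For every gray-matter voxel the Pearson correlations with all other
gray-matter voxels are computed; connections with r strictly above the
threshold (default 0.2) are Fisher r-to-z transformed (arctanh) and
summed — a weighted degree centrality.  "Sum of the connections" is
ambiguous between sum-of-z, sum-of-r and degree count; sum of Fisher-z is
the default, with `rsum` and `count` modes behind a flag for sensitivity
checks.  Correlations are computed in row blocks (configurable block
size) so memory stays O(block × n).  |r| is clipped to 1 − 1e-7 before
arctanh (synthetic data can contain exact duplicates) and clip events are
counted and logged; zero-variance voxels are dropped from the mask with a
warning rather than raised.  Seed maps average the time courses of the
seed voxels, correlate every mask voxel against that mean, and store
Fisher-z values; group statistics on seed maps are restricted to voxels
with positive connectivity, since negative connections are not analyzed.

## Group inference

Voxelwise group effects use the partial F from nested least-squares fits
(full: intercept + group dummies + covariates; reduced: intercept +
covariates), df = (G−1, N−G−k).  With no covariates this reduces exactly
to the one-way ANOVA F, which is the closed-form oracle the tests use.
Post-hoc two-group contrasts report the t of the group coefficient
(sign convention: first group minus second), evaluated inside the
restriction mask; behavior associations report the t and sign of a
clinical-score slope.  Age and a 0/1 sex indicator are the default
covariates, with no interaction terms.  F maps are thresholded
upper-tail, t maps two-tailed.  Degenerate perfect fits cap |t| at 1e12
rather than emitting infinities.

Closed-form tests from published summaries are provided for the clinical
tables: the one-way ANOVA F from per-group (mean, SD, n) and the
pooled-variance two-sample t (df = n₁+n₂−2, matching the printed degrees
of freedom).  Recomputation is limited by the one-decimal rounding of the
printed summaries; rows whose printed precision cannot pin the statistic
(notably the clock-drawing test, whose SDs of 0.4–1.1 round coarsely) are
reported but not asserted against the printed values.

## Cluster-extent correction

AlphaSim-style Monte Carlo: per iteration, an iid standard Gaussian field
on the mask is smoothed with the stated FWHM (default 4 mm, the kernel
applied to the data in the original design; smoothness is an input, not
estimated), re-standardized within the mask so the voxel p maps exactly
to a z-quantile, thresholded two-tailed, and the largest connected
component recorded.  The minimum extent is the smallest k whose null
exceedance fraction is ≤ alpha.  Connectivity defaults to 18
(face + edge, the rmm ≈ 5 convention at 3 mm voxels); 6 and 26 are
selectable.  A separate calibration routine measures the realized
familywise error on fresh null fields drawn from an independent seed; at
alpha 0.05 on a 20³ mask it lands near 0.03–0.04, conservatively inside
the binomial band around the nominal level.  The original design's
specific extents (1350/324/216 mm³) depend on an unavailable mask and
smoothness estimate and are deliberately not reproduced.

## Discrimination

Features are the values of voxels showing a significant converter
deficit (FCS and/or seed maps).  Leave-one-out cross-validation trains a
linear SVM (C = 1; kernel and C configurable) on N−1 subjects with
feature z-scoring fit on the training fold only, then predicts the
held-out subject; confusion counts pool over folds.  Accuracy,
sensitivity and specificity follow the exact rational definitions
(TP+TN)/N, TP/(TP+FN), TN/(TN+FP) with converters as the positive class.
No class reweighting is applied by default (a balanced-weight flag
exists) and there is no feature selection beyond the significance mask or
nested hyperparameter search.  Note the published performance figures
(80.6% / 70.0% / 85.7%) are mutually consistent only if the sensitivity
and specificity labels are swapped relative to the stated definitions:
the unique confusion matrix for 21 converters and 10 nonconverters with
accuracy 25/31 is (TP 18, FN 3, TN 7, FP 3), giving sensitivity 18/21 =
85.7% and specificity 7/10 = 70.0%.  The definitions are implemented
literally.

## Robustness suite

The converter-vs-nonconverter comparison of ROI-mean FCS (one scalar per
subject per planted network; voxelwise comparisons remain available
through the inference module) is re-run across correlation thresholds
0.1/0.2/0.3, with subject mean FD appended to the covariates, and with
GSR off.  One preprocessing + correlation pass per GSR setting feeds all
threshold variants, with results identical to independent recomputation.
A single sign convention — converter minus nonconverter, so a planted
deficit is negative — is used across all variants.  On default cohorts
the deficit keeps its sign across thresholds and under the FD covariate,
and is buried (|t| near 0) when the shared global signal is retained,
mirroring the reported stability pattern.

## Numerical and scale choices

Test and demonstration runs use reduced problem sizes chosen for a
single-CPU desk machine: grids of 14×14×10 to 16×16×12 voxels
(600–1200 gray-matter voxels), 100–150 frames, cohorts of 20–80 subjects,
and 200–2000 Monte-Carlo iterations.  The replicate-ordering check uses
the study's own subgroup sizes (42 NC, 31 MCI with 21 converters), since
ordering of three group means with 10-subject subgroups is genuinely
noise-limited at smaller n.  Volumes are written as uncompressed NIfTI-1
with float32 data so the run manifest's file hashes are deterministic.

## Limitations

The generator emulates the covariance structure the analysis assumes —
shared band-limited network signals, additive confounds, Gaussian noise —
not scanner physics: no spatial autocorrelation outside the planted
networks, no motion-correlated artifacts in the data (motion traces are
regressors only), no slice-timing or registration error, and no
anatomical realism in the compartment geometry.  Passing tests therefore
demonstrate correctness of the computations and calibration of the
statistics under the stated model, not performance on real scans.
Real-data results tied to anatomy (cluster coordinates, specific extents,
validation t values) are out of scope by design.
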