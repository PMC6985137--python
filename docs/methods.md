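# Methods

This note documents the models, conventions and design choices behind
`fcdstrat`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Functional connectivity density

A denoised BOLD series (voxels × frames) defines an undirected graph:
voxels `i, j` are linked iff their Pearson correlation is **strictly**
greater than 0.7. Strictness matters at the boundary and is covered by a
test; negative correlations never link (no absolute-value variant). FCD is
`log(deg + 1)` (natural log) divided by the map's median log-degree.

*Median convention.* The normalization reference is the **lower median**
(the 50th percentile with the "lower" interpolation rule), so the
reference is always an attained log-degree value and the worked 6-voxel
example `(log3/log2, log3/log2, log3/log2, 1, 1, 0)` holds for even voxel
counts. Quantiles everywhere else (IQR normalization, robust SD) use the
common linear-interpolation ("type 7") convention. A subtraction variant
of the normalization is available (`normalization="median-subtract"`),
division is the default. A map with zero median (no links at most voxels)
raises an explicit error rather than returning NaNs; constant-variance
voxels get degree 0 with a warning.

*Preprocessing.* The computational steps are: discard the first 5 frames
(165 → 160 by default); tCompCor with a noise mask of the top 2% of
voxels by temporal standard deviation after linear detrending, regressing
out the mask's top 5 principal component time courses together with an
intercept and linear trend (mask ties broken deterministically by voxel
index); zero-phase band-pass 0.01–0.16 Hz implemented as an order-4
Butterworth applied forward-backward (`sosfiltfilt`). The squared
response is ≥ 20 dB down at half the low cutoff and twice the high
cutoff. Registration, slice timing and visual QC are out of scope —
inputs are assumed voxel-aligned.

*Smoothing.* Univariate voxelwise analyses use maps smoothed with a 3-D
Gaussian kernel, FWHM 2.5 voxels (σ = FWHM/√(8 ln 2) ≈ 1.062), with
kernel weights renormalized over in-mask voxels so constants are
preserved at the mask boundary. Multivariate classifiers always use
unsmoothed maps.

*Motion exclusion.* A scan is excluded iff strictly more than 10 frames
have framewise displacement above 0.6 mm.

## Longitudinal decline

Per subject-task, decline is the OLS slope over all available visits
(2–7, yearly); fewer than two distinct time points yields a missing
value. Slopes are deliberately the simplest estimator — no mixed model —
because per-subject series are short and noisy. Tasks carry an
orientation sign so that negative slope = decline for every task; the
sign lives in the task specification, not in downstream code.

Healthy-aging correction fits `slope ~ 1 + age + male` on controls only
(age at the first functional image; sex as a 0/1 indicator) and subtracts
the full prediction, intercept included, from every subject — corrected
control slopes are centred at zero. If control sex is constant the fit
degrades gracefully to `1 + age`; a constant-age control group is an
error naming the covariate.

IQR normalization divides each task by its type-7 interquartile range,
making slopes dimensionless and combinable.

*Robust PCA.* The task × task covariance is estimated by Minimum
Covariance Determinant: the size-`h` subset (default
`h = ⌈(n+p+1)/2⌉`) minimizing the covariance determinant, found by
exhaustive enumeration when `C(n,h) ≤ 10^5` and otherwise by FAST-MCD
C-steps from 500 random starts (seeded). The raw estimate carries the
chi-square consistency factor (exactly 1 at `h = n`, where MCD reduces to
the classical covariance) and is followed by the standard one-step
reweighting at the 97.5% chi-square radius, which restores efficiency on
clean data while keeping the breakdown behavior; reweighting can be
disabled. Eigenvectors are sorted by descending eigenvalue and
sign-fixed so each component's largest-magnitude loading is positive. Two
fit variants exist: controls + pre-HD (visualization) and pre-HD only
(stratification); the top 5 components are retained by default. PC scores
are exactly decorrelated on the population whose covariance was
diagonalized (the full panel when `support_fraction = 1`).

## Discretization and classification

The robust SD is the SD of a normal with the sample's IQR:
`IQR / (2 Φ⁻¹(0.75)) = IQR / 1.34898`. Fast / slow subgroups lie below /
above `median ∓ rsd/2`; boundary ties are intermediate (conservative:
excluded from training), and a zero robust SD labels everyone
intermediate. For a normal population the cutpoints sit at ±0.5 σ, so the
expected fractions are `Φ(−0.5) = 30.9%` at each extreme and 38.3% in
between — approximately terciles.

The classifier is elastic-net-penalized logistic regression (SAGA
solver), features standardized with training-set moments. The
hyperparameter grid is λ ∈ 10^{−3..2} (8 log-spaced) × α ∈ {0.1, 0.5,
0.9}, selected by mean AUC over stratified 5-fold cross-validation inside
each training set, ties broken toward the first grid point; a reduced
grid (`ModelSpec.fast()`) is used in tests and desk-scale runs purely for
runtime. Under LOSO-CV each site is held out once; training uses
fast/slow subjects of the remaining sites; **all** held-out subjects are
scored. The decision value is the raw affine score `w·x + b` — it is
rank-equivalent to the signed distance to the hyperplane, and both AUC
and Spearman are rank statistics, so no normalization by ‖w‖ is applied.

*Leakage policy.* Every fitted preprocessing parameter — feature
standardization, age/sex weights (learned from training controls),
harmonization, CAG standardization — depends only on training-site rows.
Preprocessors are fitted on *all* rows of the training sites (controls
and intermediates included): they never receive labels, so this widens
their fit population without any label leakage, and it keeps per-site
sample sizes workable. A test asserts bit-identical fitted models when
held-out rows are arbitrarily corrupted. At apply time ComBat adjusts a
previously unseen (held-out) site using that site's own location/scale
estimates — again label-free.

*Evaluation.* Site AUCs come from the rank (Mann-Whitney) statistic and
are averaged across sites; a bootstrap (resampling subjects within site,
default 10^5 resamples, reduced to 10^3 in tests) reports the median
site-averaged AUC. Sites lacking a class are skipped for AUC with a
warning but retained for Spearman; sites with fewer than 3 subjects are
skipped for Spearman. Per-site Spearman correlations are pooled as
`tanh(mean(atanh(ρ_site)))`. Permutation p-values permute labels
independently within site and use the add-one rule
`p = (1 + #{null ≥ obs}) / (1 + n_perm)`, so p is never zero; the default
10^5 permutations are reduced to 10^3 in tests. CAG repeat length can be
appended as one standardized extra feature (standardization fit on
training rows).

## Reliability

Fingerprinting correlates each subject's baseline map with every
subject's follow-up map; the self-match's descending rank is recorded,
with ties broken **against** the self-match (worst rank). The
identification rate is the fraction of rank-1 self-matches; chance is
1/N (0.65% at N = 153). Transition matrices condition the follow-up
confusion outcome (TN/FP/FN/TP, threshold 0 on the affine score) on the
baseline outcome; each subject's two maps are scored by the model whose
held-out site was theirs. The null permutes follow-up outcomes within
group (group-preserving), the chance matrix is the mean permuted
transition matrix, and diagonal cells get two-sided add-one p-values.

## Confound controls

*ComBat.* Per voxel, standardize by the grand mean and the pooled
within-site scale, estimate per-site location γ and scale δ, adjust, and
de-standardize. No biological covariates are included — by design, so
class information cannot leak through the harmonization. Two variants:
`method="eb"` (default) applies the classic parametric empirical-Bayes
shrinkage (normal prior on γ, inverse-gamma on δ², moment-matched
hyperparameters, iterated to convergence; per-site δ̂² uses the n−1
convention of the reference implementations, and a unit test cross-checks
against Bioconductor's `sva::ComBat`). `method="exact"` uses the raw
location/scale estimates; it removes site means and variances exactly and
is exactly idempotent (fit-and-apply twice equals once to machine
precision), which the EB variant is not — shrinkage always leaves a small
residual, so EB re-application is only approximately stable. A single
site is returned unchanged by construction.

*GMC residualization.* Per voxel, `FCD ~ 1 + GMC` across subjects;
residuals are the atrophy-controlled maps. Constant-GMC voxels fall back
to mean-centering with a warning. The same LOSO machinery applied to GMC
maps alone is the negative control.

*Motion.* The per-feature linear weight of mean framewise displacement is
learned from controls and only the slope term
`w·(fd − mean control fd)` is subtracted, preserving control means.

## Statistical primitives

Mann-Whitney U is reported as `min(U_x, U_y)`; for combined n ≤ 20 the
two-sided p doubles the exact lower tail of the enumerated permutation
distribution (tie-safe), capped at 1; larger samples use the
tie-corrected, continuity-corrected normal approximation. BH-FDR is the
step-up rule with monotone-enforced adjusted values. Spearman is Pearson
on average ranks with `t = ρ√((n−2)/(1−ρ²))`. Voxelwise maps run the
test per voxel over in-mask voxels, BH-correct, and export
`sign(effect) × (−log10 q)`.

## Synthetic cohort: what it emulates, and what it does not

The generator is a pure function of (config, seed); every scan's random
stream depends only on (seed, subject index, visit), so subsets
regenerate identically. Defaults mirror a four-site premanifest cohort:
79 controls (49 ± 11 y, 30/79 female) and 74 carriers (42 ± 10 y, 34/74
female, CAG 43 ± 2, integer, CAP = 100·age·(CAG − 35.5)/627). A scalar
latent decline factor (carriers only; mean 1.0, SD 0.5, correlation ≈ 0.3
with CAP; controls exactly 0) drives both the task-slope loadings and the
imaging effect; it is emitted as ground truth and never consumed by
analysis stages. A multi-factor option exists for probing stratification
beyond the first component.

BOLD series are linear mixtures of: five shared network latents
(amplitude 2, giving within-network correlations just above the link
threshold); a subject-stable fingerprint pattern (loadings fixed across
visits, amplitude 0.6 by default); a decline-linked **hub** component in
10% of voxels — each hub voxel has a recruitment onset uniform in
[0, 2.5] and its loading grows (saturating at one unit of excess) once
the subject's latent factor passes it, so the *breadth* of recruited,
mutually-correlated hub voxels grows with decline and the planted effect
stays graded instead of saturating; a pre-HD group signature on a
separate 5% voxel set; a per-site gain on a fixed spatial pattern; a
motion-locked artifact scaled by the visit's mean framewise displacement
(motion distributions identical across groups by default); and unit
white noise. A 3% voxel subset carries high-amplitude physiological
noise (SD 5) — deliberately the highest-variance compartment, as CSF is
in real data, so the tCompCor variance mask isolates it rather than the
neural signal. The first 5 frames carry a decaying global offset
(unsteady magnetization analogue). Grey-matter maps are a smooth base
pattern plus subject noise, minus a decline-linked atrophy term on a
region overlapping the hub set, clipped to [0, 1]; the default atrophy
scale is mild so grey matter alone carries little group signal.

Task visit counts are uniform in [2, 7] per subject-task; scores follow
`baseline + slope·t + noise` with
`slope = sign · (aging + sex·offset + loading·latent)` in raw units, and
two tasks are error counts whose raw scores rise under decline.

What the generator does **not** emulate: spatial autocorrelation of real
BOLD beyond the planted patterns, registration error, scanner drift
differences by vendor, non-linear decline trajectories, missing-at-random
visit structure correlated with disease severity, and realistic effect
sizes — the planted high-strength hub effect is far stronger than any
plausible clinical signal. Passing tests therefore demonstrate that the
pipeline recovers structure it is pointed at, is calibrated under nulls,
and leaks nothing across sites; they do not certify effect sizes on real
cohorts.

## Problem sizes and numerics

Desk-scale defaults: 1,000 voxels on a 10×10×10 grid and 165 frames
(160 after trimming) per scan, against tens of thousands of voxels in a
full-resolution analysis; tests and the acceptance script use cohorts of
40–153 subjects, permutation/bootstrap counts of 10^2–10^3 (10^5 remains
the configurable default), and the reduced hyperparameter grid. Chance
calibration of the null AUC is asserted as a mean over hundreds of
permutations, and the zero-effect pipeline null is averaged over eight
seeded replicates because a single 74-subject run has an AUC standard
error near 0.1. Degenerate inputs (constant voxels, zero IQR, single-class
training sets, sites lacking a class) warn or raise as documented above
rather than propagating NaNs.
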