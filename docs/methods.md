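# Methods

This note documents the models, conventions and design choices behind
`ptemark`, and what the synthetic cohorts do and do not establish.

## The variance-coding premise

Traumatic brain injuries land in different places in different patients, so
a group of TBI patients who later develop post-traumatic epilepsy (PTE) is
not expected to differ from non-PTE patients in the *mean* of any voxel-wise
map; a higher frequency of lesions (or of functional disturbance) in a
region instead raises the across-subject *variance* there.  Every group
statistic in the package is therefore variance-directed: the voxel-wise test
is a one-sided variance-ratio F with the PTE group in the numerator, and the
synthetic generator plants group differences as prevalence and variance
effects, not mean shifts.

## Synthetic cohort generator

The generator emulates preprocessed, skull-stripped, atlas-registered data:
every subject lives on the same grid with an identity affine, and anatomy is
a fixed smooth field plus voxel noise.  Defaults follow the emulated study
design: 36 subjects per group, 153 resting-state volumes at a repetition
interval of 2 s, ALFF band 0.01–0.1 Hz.  The grid default is 64×64×16 — a
desk-scale stand-in for a 1 mm atlas grid that preserves slice-wise VAE
training; all sizes are configurable.

**Parcellation.** 15 lobe-level regions are the Voronoi cells of fixed
anatomically-placed seed points inside an ellipsoidal brain mask, which
makes every region contiguous and the tiling deterministic.  Grids too small
to give every region 27 voxels are rejected.

**Lesions.** Per region and subject, a Bernoulli draw with the group's
prevalence plants one hyperintense blob, centered uniformly in the region.
Blobs are anisotropic ellipsoids — in-plane semi-axis 5 voxels,
through-plane 2 — mirroring the thick-slice acquisitions this grid emulates
(≈ 2.5 cm contusions at ~2.5 mm effective in-plane spacing, sections ~6 mm);
an isotropic small sphere would be thinner than the mandated 7×7 median
filter's survival size in most slices and would also be impossible to place
in the thin inferior regions of a 16-slice grid.  Contrast is
`lesion_intensity × noise_sd` (default 3× the anatomical noise).  Blobs that
would leave the brain are shrunk to fit, with a warning.  Default prevalence
is 5% everywhere, raised to 45% for PTE in bilateral temporal, right
occipital and cerebellum — the regions where group effects are planted.

**fMRI.** 15 latent ROI signals are drawn from a multivariate normal with a
distance-decaying base correlation matrix, perturbed per group by
`connectivity_shift`, projected back to a positive-definite correlation
matrix by eigenvalue clipping at 1e-6 and diagonal re-normalization, then
band-pass filtered to the ALFF band (FFT bin zeroing) and standardized.
Identical per-channel filtering preserves the zero-lag correlation
structure.  Each ROI latent is scaled by √m where m is a per-subject
band-power multiplier, m ~ max(1 + s·z, 0.05) with s² scaled by
`alff_variance_ratio` for the PTE group — so the across-subject ALFF
variance ratio between groups equals the configured ratio (up to
truncation).  Each in-brain voxel is its ROI latent plus white noise of sd
`fmri_noise_sd` (default 1, matching the latent scale).  A requested pair
correlation near ±1 cannot survive the PD projection exactly, because the
two regions correlate differently with the remaining 13; recovery is
therefore checked against the repaired target matrix.

**Seeding.** Per-subject streams derive from
`SeedSequence([cohort_seed, subject_index, stream_tag])`, so a single
subject can be regenerated in isolation, and identical configurations yield
bitwise-identical cohorts.  The default cohort holds ~3 GB of time series if
fully materialized; `iter_subjects` streams one subject at a time and is
what the pipeline and the acceptance script use.

**What the generator does not model:** inter-subject anatomical variability
(the smooth base field is shared; only noise and lesions differ), MR physics,
motion or physiological artifacts, registration error, multi-site effects,
demographic covariates.  Passing tests therefore establish that the pipeline
recovers effects *of the planted kind under idealized registration*, not
performance on real scanner data.

## Lesion scoring

Slices (third grid axis) are linearly resampled to the model's input size
(default 128×128), decoded from the latent mean — inference never samples,
so score maps are deterministic — and scored as |original − decoded|.  The
7×7 median filter is applied at the model resolution, where the error is
computed, before resampling back to the native grid.  The score uses the
absolute difference by default; a `positive` mode keeps only hyperintense
residuals.  Inputs are histogram-matched to a lesion-free reference subject
by monotone quantile mapping of in-mask intensities (a constant input maps
to the reference median).

The VAE is three stride-2 conv blocks (widths 32/64/128, kernel 4, batch
norm + ReLU), fully connected heads for the latent mean and log-variance
(latent 32), and a mirrored decoder (fully connected, three deconv blocks,
a final stride-1 deconv, sigmoid output).  Training minimizes
0.5‖x − x̂‖² + `kl_weight`·KL with Adam (lr 2e-3, global-norm gradient clip
1e4 to tame early spikes); everything — initialization, shuffling,
reparameterization noise — is seeded.  The layers are implemented directly
in NumPy (im2col convolution, adjoint-form transposed convolution, explicit
batch-norm backward); a finite-difference gradient check in the test suite
pins the backprop.  Latent width, channel widths and epoch count are
declared defaults, not fitted quantities.

**Binarization.** At each in-brain voxel a one-class SVM (RBF) is fit on the
across-subject score sample with contamination `nu` (default 0.1).  The
kernel bandwidth is set wide — γ = 1/(100 × median pairwise squared
distance), about 7 robust SDs — so the decision approximates a kernel
density ranking of the scalar sample: a single extreme subject is reliably
flagged and the flagged fraction stays near `nu` for well-behaved samples.
Fitting on the sorted sample and predicting by value makes the result
exactly equivariant under subject permutation.  Known limitation: when many
subjects are lesioned at the same voxel they form their own dense cluster,
which a density ranking can partially absorb — some lesioned subjects may
escape flagging there.  Voxels where all subjects score identically flag no
one.

## ALFF and connectivity conventions

ALFF is band *power*, not its square root: the demeaned periodogram is
normalized so that summing all bins returns the series variance, and bins
with band_low ≤ f ≤ band_high (inclusive) are summed.  A pure in-band
sinusoid of amplitude A thus yields ≈ A²/2.  Only relative comparisons
matter downstream, so the normalization choice is a fixed convention.
Connectivity uses Pearson correlation of ROI-mean series; |r| is clipped at
1 − 1e-7 before the Fisher z transform so features stay finite.  No
additional band-pass filtering or nuisance regression precedes connectivity:
the synthetic series are generated clean.

## Permutation inference

The same label permutation is applied to every voxel of a map in each
iteration, preserving spatial correlation.  Monte-Carlo p-values use the
(1 + b)/(nperm + 1) convention and are never zero; when the number of
distinct labelings C(n_A+n_B, n_A) is at most `nperm`, all labelings are
enumerated instead and p = #{F\* ≥ F}/n_labelings, identity included.  The
observed statistic is recomputed with the same running-sums formula used for
the permuted statistics so that the identity labeling ties exactly in
floating point.  Zero-variance denominators yield an infinite F treated as a
tie against permuted infinities; a 0/0 voxel reports F = 1.  BH-FDR is
applied across in-brain voxels only (statsmodels' step-up implementation
behind `bh_fdr`), and the lobe-wise table corrects across regions separately
for the lesion (rank-sum) and ALFF (permutation-F) measures.  The rank-sum
test uses exact enumeration for m+n ≤ 12 without ties, otherwise the
tie-corrected normal approximation (scipy).

At n = 36 per group the one-sided variance test's power against a ratio of 4
under the BH rank-1 threshold (p ≤ 0.05/15) is about 0.85–0.9 — the
calibration tests allow 3 binomial SDs of Monte-Carlo slack around that
analytic value rather than asserting a point power.

## Classification

One CV "repeat" is a complete leave-one-pair-out pass under a freshly
randomized PTE↔non-PTE pairing (the study-scale default is 1000 repeats;
tests and the acceptance run scale this down).  Within each outer fold,
standardization and PCA are fit on the training subjects only, and the PCA
dimension plus model hyperparameters are selected by inner stratified k-fold
AUC; PCA components are nested, so one decomposition at the largest grid
value serves every candidate dimension.  AUC is computed from pooled
out-of-fold decision scores, since a per-pair AUC is degenerate (0/0.5/1).
The AUC sd is across repeats.  Grids: kernel-SVM C ∈ {0.1, 1, 10} and γ =
scale-heuristic × {0.1, 1, 10}; PCA ∈ {5, 10, 20, 40} (clipped to the
training size); random forest 500 trees, depth ∈ {none, 5}; MLP fixed at
32/16/16 ReLU with early stopping (disabled below 24 training subjects,
where a stratified validation split is impossible).

The permutation null permutes labels before a full CV pass; the observed
AUC sample is compared to the null sample with a two-sided rank-sum test,
and a kernel density summary is exported for plotting.  Feature importance
is the positive part of linear-SVM coefficients fit on the standardized full
table in PCA space and back-projected; connectivity features split their
importance equally between their two regions.  This back-projection and the
split rule are package conventions.  The learning curve repeats CV on random
balanced subsets per size (sizes below 6 subjects are skipped), and the
extrapolation is a least-squares quadratic in n through the last k points,
clipped to [0, 1].

## Pipeline

`run_pipeline` executes cohort → lesions → features → stats → classify.
Each stage writes a manifest with a hash of its configuration chained with
its upstream stage's hash; a rerun with the identical configuration is a
no-op, and any stage that does re-run forces its descendants to re-run.  The
lesion stage trains the VAE on slices from extra lesion-light subjects drawn
from an independent seed stream (non-PTE prevalence), mirroring training on
a separate TBI sample, and histogram-matches every cohort subject to a
lesion-free reference before scoring.  Volumes are written as NIfTI with an
identity affine: real-data users must register their volumes to a common
grid beforehand — the package deliberately contains no registration,
surface extraction or atlas tooling.

## Problem sizes in the shipped checks

The acceptance computations use: the full default cohort (36+36, 64×64×16,
T=153) for structural checks; 500 null maps of 2000 voxels at n=20/group
(nperm=1000) for type-I calibration; 500 replicates of 500 mixed hypotheses
for FDR control; a 5-epoch VAE trained on ~900 slices from 64 subjects and
scored on ~10 lesioned subjects (pooled voxel ROC) for detection power; and
the strongly-planted cohort at n=20/group (32×32×12) with 8 CV repeats and
200 permutation nulls for classifier calibration and recovery.  These sizes
are the package's chosen desk-scale study conditions; all are parameters.
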