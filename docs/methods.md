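# Methods

## Problem and model

Gliomas with an isocitrate dehydrogenase (IDH) mutation behave differently
from IDH-wildtype tumours, and the mutation leaves traces in diffusion MRI:
wildtype tumours tend to show lower mean diffusivity (denser cellularity)
and altered anisotropy. The package predicts the binary IDH label from
imaging alone, as a three-stage pipeline: deterministic image
preparation, a fixed (not trained) convolutional feature extractor with
statistical pooling, and a calibrated support-vector classifier evaluated
by nested cross-validation. The convolutional stack is used purely as a
texture filter bank; no gradients flow anywhere.

## Volume preparation

All modalities are resampled to a common isotropic grid (default 1 mm) by
trilinear interpolation in world coordinates; binary masks use
nearest-neighbour so they stay binary. Output shape is
ceil(shape·spacing/target). Intensities are then z-scored with the sample
(n−1) standard deviation over the volume's nonzero support — a support
choice that is robust to zero-padded background and applies uniformly to
synthetic and skull-stripped clinical data; a caller can pass an explicit
support mask instead. Resampling precedes normalisation so that the
statistics describe the grid the features are computed on. Co-registration
is an upstream precondition: the package verifies grid congruence across a
subject's modalities and raises on disagreement rather than registering.

Masked volumes are cropped to the ROI bounding box dilated by a margin
(default 8 voxels, clipped to grid bounds) so the conv stack's receptive
field sees tumour-boundary context. Voxels outside the ROI are zeroed
before cropping; a property test asserts no nonzero voxel survives outside
the mask.

## Diffusion tensor estimation

The signal model is mono-exponential: S(b, g) = S₀ exp(−b gᵀDg), fitted per
voxel by ordinary least squares on the log signal using the unweighted
(b < 50 s/mm²) volumes plus the single highest-b shell; other shells are
ignored by default (`shell="all"` uses everything). Log-linear LSQ is the
simplest estimator adequate for the SNR regimes simulated here; weighted or
nonlinear variants are out of scope. Non-positive signals are floored at
10⁻⁶·S₀ before the log. The fitted tensor is eigen-decomposed; negative
eigenvalues (noise) are clamped to zero before FA and MD are computed, and
FA is clipped to [0, 1]. An all-zero tensor has undefined FA and maps to 0.

The statement that FA/MD derive from "the average of all 30 directions of
the highest b-value" admits two readings: a tensor fit restricted to the
highest shell (implemented as the default) or a directional average of the
signals themselves (an apparent isotropic diffusivity; exposed as
`directional_average=True`, FA ≡ 0 by construction). The default is a
choice, not an established fact about the source protocol.

## Deep-radiomics features

The extractor is the convolutional prefix of VGG16: 3×3 kernels, stride 1,
same-padding, ReLU after every conv, 2×2/stride-2 max-pool between blocks
(ceil-mode at odd edges). Layer 0 is the raw masked input; "first four conv
layers" means conv1_1, conv1_2, conv2_1, conv2_2; a fifth layer (conv3_1,
256 channels) exists for depth sweeps. The forward pass is evaluated
directly in NumPy (sliding-window im2col + BLAS matmul), which keeps the
package dependency-light and exactly reproducible.

Weights: the default is He-initialised seeded random filters with zero
biases — random conv projections followed by summary statistics are an
effective texture descriptor, and the statistical pipeline downstream is
weight-agnostic. An `.npz` checkpoint of ImageNet VGG16 kernels can be
supplied instead (`weights_source="checkpoint:<path>"`); its 3-channel
first layer is fed the grayscale slice replicated ×3. No ImageNet mean/std
rescaling is applied on top of the subject-level z-score.

3D volumes enter the 2D network one axial slice at a time: every slice
intersecting the ROI is processed, and each channel's activations are
pooled across slices *before* statistics, so the vector length is
independent of tumour size. The statistics support is all activation values
of the cropped slices (not re-masked at depth), since receptive fields
deliberately blend boundary context.

The six per-channel statistics are mean, median, sample (n−1) SD, 5th and
95th percentiles with linear interpolation (rank r = 1 + q(n−1)), and
non-excess kurtosis (normal → 3, the MATLAB convention). A zero-variance
channel is degenerate: kurtosis is reported as 0 with a flag. Vector order
is modality-major, then layer, then channel, then statistic; age, when
requested, is appended raw as the last element — per-column
standardisation inside the classifier (fitted on training folds only)
makes this equivalent to z-scored age without leaking cohort statistics.

## Classification

A soft-margin RBF-SVM (scikit-learn's libsvm backend, stopping tolerance
1e-8 so solutions are label-swap symmetric) with per-class penalty C·w;
default weights mutant:1, wildtype:3, matching the ≈70/30 cohort imbalance.
Feature columns are z-scored with training-fold statistics. (C, γ) come
from a grid search over the standard logarithmic grid C ∈ 2^{−5..15},
γ ∈ 2^{−15..3} (step 2²), scored by F1 on the minority wildtype class
averaged over stratified 5-fold inner CV (each validation part is 20% of
the training set); ties break toward smaller C then smaller γ. Recall is
available as an alternative metric.

Posterior probabilities come from Platt's sigmoid p = 1/(1 + exp(A·f + B)),
fitted by minimising the regularised negative log-likelihood with smoothed
targets t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2) on *out-of-inner-fold* decision
values — calibrating on training-set decision values is optimistically
biased. Ensembles average calibrated probabilities arithmetically.

## Evaluation

Outer folds are stratified and seeded (default K=5). Out-of-fold
probabilities are pooled across folds into one confusion-count and ROC/AUC
computation — the reading under which per-model confusion counts sum to
the cohort size. The decision threshold on the calibrated mutant
probability is 0.5. AUC is the pairwise concordance
P(p₊ > p₋) + ½P(p₊ = p₋), computed by midranks and verified against a
brute-force all-pairs oracle. Paired model comparisons use DeLong's test on
the pooled probabilities, with a seeded sign-flip permutation test as a
small-sample fallback; p-values are Benjamini–Hochberg adjusted across the
requested pairs. (BH is monotone and dominates the raw p-values but is not
idempotent; the tests assert the true properties.)

## Synthetic phantoms

Each subject is a small isotropic grid (default 48³ at 1 mm) holding five
volumes. Backgrounds are Gaussian random fields smoothed to a 4 mm FWHM
correlation length plus unsmoothed voxel noise (SD 0.3 of the background
SD). The tumour is an exact ellipsoid (default semi-axes 10×8×7 voxels,
jittered per subject) whose interior means shift by class: FA background
0.30 with mutant −0.08 / wildtype +0.10; MD background 0.8×10⁻³ mm²/s with
mutant +0.50×10⁻³ / wildtype +0.12×10⁻³ (wildtype lower MD, higher FA than
mutant, the direction reported for IDH-wildtype biology); structural
modalities get small class-dependent hyper-/hypo-intensity shifts. These
defaults give comfortable class separation at n=100 for the recovery runs.
The low-contrast cohort used in the class-weighting comparison scales all
class shifts by 0.05, which places its nested-CV AUC near 0.8 — the
separability regime clinical cohorts show — so the two classes genuinely
overlap and the weighting has something to trade.

Ages are truncated normals on [18, 90]: mutant 39.1±8.7 y, wildtype
55.1±13.5 y; the mutant fraction defaults to 146/206 and class counts are
exact by rounding. Every output is a deterministic function of
(spec, seed, subject_id).

FA/MD are produced analytically by default; `fa_md_route="dwi"` instead
builds an axially symmetric tensor field with the prescribed FA/MD
(α = FA/√(3−2FA²), λ₁ = MD(1+2α), λ₂ = λ₃ = MD(1−α)), simulates a
31-volume Fibonacci-sphere acquisition (1 b0 + 30 directions at
b=1000 s/mm²) with optional Rician noise, and runs the tensor fit — the
round trip is exact to 1e-9 without noise.

What the phantoms do *not* emulate: MR physics (k-space, bias fields,
partial volume), scanner effects beyond a hook for per-scanner offsets,
anatomical structure, or registration error. Passing tests therefore
demonstrate algorithmic correctness and statistical behaviour of the
pipeline, not clinical performance; the clinical AUCs of the motivating
setting are not reproducible without patient data.

## Problem sizes and numerical choices

The recovery runs use 100-subject cohorts at 48³ (strong, zero-contrast and
label-permuted) and a 60-subject low-contrast cohort; these sizes give
stable AUC estimates while the full suite runs in minutes on one CPU. The
conv forward pass is float32; statistics and everything downstream are
float64. Determinism: every stochastic component (generator, fold plans,
grid search, permutation tests, heatmap channel choice) is driven by an
explicit seed, and repeated runs are bit-identical.

## Known limitations

- The pretrained-checkpoint path expects kernels as `.npz`; no checkpoint
  ships with the package and none is downloaded.
- Platt calibration assumes both classes present and non-degenerate
  decision values; single-class folds raise rather than guess.
- The DeLong variance estimate is asymptotic; for very small strata use the
  permutation method.
- Scanner harmonisation, skull stripping, registration and bias-field
  correction are out of scope and assumed done upstream.
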