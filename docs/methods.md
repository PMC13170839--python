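# Methods

This note records the models, the parameter choices that matter, and the
limits of what the synthetic-phantom experiments establish.

## Phantom model

Each case is a 64×64×32 voxel volume at 1 mm isotropic spacing containing
an ellipsoidal "sella" background and one ellipsoidal tumor (radius drawn
from 8–13 mm, mild eccentricity 0.85–1.0, small center jitter). Tissue
parameter maps are built first, signals second:

- **ADC** (mm²/s): background 0.85×10⁻³ with slow spatial modulation;
  tumor ADC drawn uniformly from 0.9–1.3×10⁻³ (soft) or 0.5–0.8×10⁻³
  (fibrous) — the ranges reflect the restricted diffusion of collagen-rich
  stroma — plus a small smooth within-tumor modulation.
- **S0 / T2**: background ≈ 100 / 60 intensity units. The tumor's internal
  texture is a Gaussian random field shared between the b = 0 and T2
  volumes; fibrous tumors get correlation length 1–2 mm and amplitude 12
  (≈ 2× the soft class at 4–6 mm, amplitude 6). Fibrous tumors are
  T2-hypointense (base 90 vs 140 for soft), the classical appearance.
- **DWI b = 1000**: computed voxel-wise as `S0 · exp(−1000 · ADC)` before
  noise; b in s/mm², ADC in mm²/s, so the exponent is dimensionless and a
  unit error anywhere breaks the exactness test.
- **Noise**: Rician (magnitude of a complex signal with i.i.d. Gaussian
  channel noise, σ = 2, i.e. SNR ≈ 50 against S0 = 100), applied to T2,
  b = 0 and b = 1000; the stored ADC map is the noiseless truth.

Determinism: every random draw derives from `(seed, stream, case_index)`
through NumPy's `SeedSequence`, so a fixed seed reproduces volumes
bit-identically across runs and platforms.

The class signal is therefore planted twice — in mean ADC (which survives
into b = 1000 intensity) and in texture statistics — without dictating
*which* radiomic features must win. What a green end-to-end test
establishes is that the pipeline can find and exploit a genuine class
difference without leakage; it says nothing about effect sizes in real
adenomas, scanner artifacts, partial-volume boundaries, or segmentation
variability, none of which are simulated.

## Translation networks

The generator is a U-Net (default depth 2, 16 base channels) whose
encoder/decoder levels carry *attention residual blocks*: two 3×3 convs
with instance normalization, gated by squeeze-excitation channel attention
(global average pool → bottleneck → sigmoid scale), added residually. Skip
connections pass through the same attention gate. Output is tanh-bounded;
slices live on [−1, 1] (mapped from the 0–255 display normalization). The
discriminator is a PatchGAN (strided 4×4 convs to a patch score map).

Training is unpaired CycleGAN: least-squares adversarial losses, cycle L1
weighted λ_cyc = 10, identity L1 weighted λ_id = 5, Adam (lr 2×10⁻⁴,
β₁ = 0.5) with linear decay over the second half, replay buffer of 50
generated slices. Slices without tumor foreground are dropped. One model
per source→target pair; nothing is shared between the three targets.

Everything runs on a small in-repo reverse-mode autodiff engine over NumPy
(im2col + GEMM convolutions), gradient-checked against central finite
differences. Float32 throughout; inference is deterministic, and training
is deterministic given the seed because no nondeterministic kernels exist.
The exact attention-block wiring is a design choice isolated behind
`GeneratorSpec`, so an alternative block can be substituted without
touching the training loop.

**Scale.** The shipped *desk* profile (64×64, 16 channels, ≤ 30 epochs;
the worked example and acceptance script use 5) exists so the entire
pipeline runs on one CPU in minutes. It demonstrates the machinery —
synthetic b = 1000 beats the copy-the-source baseline — but remains far
from the MSE < 80 / PSNR > 30 dB / SSIM > 90 regime that full-scale
training on real images reaches. The *full* profile (depth 3, 32 channels,
100 epochs) is provided but untested at scale here.

## Quality metrics

MSE/PSNR/SSIM are computed on the 0–255 scale (whole-slice by default; a
region mask restricts MSE/PSNR when masked replication is wanted). SSIM
uses the Gaussian-window formulation (σ = 1.5, width 11,
C1 = (0.01·255)², C2 = (0.03·255)²) per axial slice, averaged, reported
×100. Cohort summaries carry normal-approximation 95% CIs on per-case
means (at cohort sizes ≥ 30 the t correction is under 5% and the z form
matches the bootstrap; the suite verifies this). Display windows default
to the volume's 1st–99th percentile when none are given — windows are an
operator setting with no published values, and percentile windows are
reproducible and outlier-robust.

## Radiomics battery

526 features: 13 shape, 18 intensity, 39 texture, 456 wavelet. Published
counts fix only the family sizes; the concrete lists follow the
IBSI-style canon and are pinned name-by-name in
`synthrad.radiomics.FEATURE_NAMES`. Choices worth knowing:

- The 39-texture split is 22 GLCM + 13 GLRLM + 4 NGTDM — a documented
  decision, not a published list. GLCM pools the 13 symmetric distance-1
  3D offsets; GLRLM pools runs over the same 13 directions; NGTDM uses the
  26-neighbourhood.
- Discretization: 32 fixed bins over the in-mask range (configurable).
- Wavelet: single-level undecimated 3D separable transform with periodic
  boundary, default **Haar** basis. The Haar pair is exact, short-support
  and dependency-free; no wavelet library is required. Any orthogonal
  lo/hi filter pair can be injected instead.
- Shape: surface area from marching cubes on the lightly smoothed
  (σ = 0.5) binary mask — unsmoothed meshing reads digital spheres ~7%
  high (staircase bias); axis lengths are 4√λ of the physical-coordinate
  covariance eigenvalues.
- Degenerate inputs fail loudly: empty masks, and single-voxel or
  single-grey-level regions for texture, raise typed errors rather than
  returning NaNs.

## Feature selection

Stage 1 ranks by the lasso path (scikit-learn `lasso_path`): the earlier a
coefficient activates on the decreasing-λ path, the more important the
feature; ties break by |w| at the smallest λ, then name. (A perfectly
duplicated column is *suppressed* by the lasso once its twin is active —
only independently-noisy copies of a signal both rank early; the tests
document this.) Constant columns rank last with a warning. Inputs must be
standardized on training rows; this is checked, not assumed.

Stage 2 is sequential forward selection along the ranking, scored by
stratified 10-fold CV accuracy of a sparse-representation classifier
(SRC): the query is coded over L2-normalized training-sample atoms by
**non-negative** L1-regularized least squares and assigned to the class
with the smaller class-restricted reconstruction residual. Non-negativity
matters: standardized two-class data is approximately antipodal, and
signed coefficients would let either class reconstruct any query by sign
flips, collapsing SRC to chance (verified empirically). The penalty is
λ = f·λ_max with f chosen per outer fold by nested 5-fold CV over
f ∈ {0.01, 0.05, 0.2} on a pilot prefix of the ranking — one nested
search per fold rather than per subset size, keeping the procedure honest
to the outer loop at ~50× less cost. The chosen subset is the smallest
size maximizing mean CV accuracy. The interface never receives test rows,
making train/test leakage structurally impossible; a noise-substitution
test asserts it anyway.

## Classifier and evaluation

The MLP default is one hidden layer of 16 ReLU units with L2 10⁻³ —
deliberately small for n ≈ 100 cohorts. Early stopping on a held-out
fraction of the training rows is available but **off by default**: at
these cohort sizes the validation accuracy saturates at the first epoch
and scikit-learn then restores that near-initial snapshot, which we found
could silently invert an otherwise perfectly separable fit (train
accuracy ~0.55 on a cleanly separated feature). Regularization is carried
by the penalty and the small capacity instead. Standardization is fitted
on train and frozen. Thresholding
defaults to 0.5. Positive classes are fixed by constants: *fibrous* for
consistency, *synthetic* for reader studies.

AUC uses the Mann–Whitney form with half-credit ties (verified identical
to the trapezoid of the ROC polygon); CIs are 2000-replicate stratified
bootstraps. DeLong's test uses structural components. Category-free NRI
and IDI follow the defining formulas with asymptotic-normal CIs/p-values;
IDI is verified against the discrimination-slope identity. Proportions
get Wilson intervals. Decision curves use net benefit
`TP/n − (FP/n)·t/(1−t)`; calibration uses equal-frequency bins plus
logistic recalibration slope/intercept.

Reader-study summaries are computed from confusion-table cells, with
"synthetic" positive; when externally printed per-reader values are
supplied, any disagreement with the table's own arithmetic is flagged
rather than silently adopted.

## Known limitations

- Phantom realism is deliberately minimal (no anatomy, no scanner
  artifacts, no inter-rater mask variability); absolute metric values are
  not comparable to real-data studies.
- The desk GAN profile trades fidelity for CPU-minutes; the full profile
  has not been benchmarked here.
- SRC behavior is sensitive to dictionary size in very low dimensions
  (subset size 1–2); the non-negative coding mitigates but does not remove
  this.
- The wavelet family uses in-mask statistics of full-volume filtered
  sub-bands; filters straddle the mask boundary by construction, so those
  features are not strictly mask-internal.
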