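# Methods

This document describes the model implemented by `dtienhance`, the choices
made where the underlying approach leaves freedom, and the known limitations.

## 1. Problem setting

Diffusion tensor imaging (DTI) models the diffusion-weighted MR signal in
each voxel with a symmetric, positive-definite 3×3 tensor **D**:

```
S(b, g) = S0 · exp(−b gᵀ D g)
```

where `b` is the diffusion weighting (s/mm²) and `g` a unit gradient
direction. **D** has six free coefficients, stored throughout the package in
the order `(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)` (`tensor.COEFF_NAMES`). Together
with the unknown `log S0` this gives seven unknowns per voxel, so a minimal
acquisition is one b=0 volume plus six non-collinear diffusion directions.

Fitting from only six directions is exactly determined but noise-fragile:
scalar maps derived from the eigenvalues — fractional anisotropy (FA), mean /
axial / radial diffusivity (MD, AD, RD) — are visibly biased and noisy
compared with fits from dense schemes (60–90 directions). The package
implements a learning-based enhancement: a 3-D convolutional network maps the
minimal acquisition (plus a structural T1-like channel) to the six tensor
coefficients a dense fit would have produced.

## 2. Tensor fitting

`tensor.fit_tensor` performs ordinary least squares on the log signal. The
design row for a measurement `(b, g)` is

```
(−b gx², −2b gx gy, −2b gx gz, −b gy², −2b gy gz, −b gz², 1)
```

with the trailing 1 multiplying `log S0`. The fit uses a single pseudoinverse
shared across voxels (`numpy.linalg.pinv`), applied to masked voxels only;
voxels with any non-positive signal are treated as dead and left zero. Rank
deficiency (coplanar directions, missing b=0) raises `DegenerateSchemeError`
rather than producing silently garbage coefficients.

Scalar maps clamp eigenvalues at zero before computing FA/MD/AD/RD so that
noise-driven negative eigenvalues cannot produce FA > 1 or negative
diffusivities. FA of an exactly isotropic tensor is defined as 0.

## 3. Direction subsampling (Kennard–Stone)

Subsets of a dense scheme are chosen with a maximin (Kennard–Stone style)
rule on the hemisphere metric

```
d(a, b) = sqrt(2 − 2 |a·b|)
```

which treats antipodal directions as identical (diffusion is symmetric in
±g). The first point is the one furthest from the centroid direction under
this metric; each subsequent point maximises its minimum distance to the
already chosen set. Ties break on the lowest index, making the procedure
deterministic and the k-subset a prefix of the (k+1)-subset (nesting).
`random_ks_sample` replaces only the first pick with a uniformly random one
(a single `rng.integers(n)` draw) and then proceeds greedily, which is how
the "random" input variants for the generalisation harness are produced.

## 4. Phantom generator

No real imaging data ships with the package, so training and evaluation use
a synthetic brain-like phantom (`phantom.build_phantom`):

- An ellipsoidal "brain" mask inside the requested grid.
- A set of white-matter tracts — cylinders with per-seed jittered oblique
  orientations, centres and radii — embedded in isotropic "grey matter"
  background. Tract voxels get axially symmetric tensors with prescribed FA
  and MD (via `axially_symmetric_eigenvalues`, which inverts the closed-form
  FA of a (λ∥, λ⊥, λ⊥) tensor); background voxels are isotropic.
- A T1-like structural channel with distinct tissue intensities.
- `simulate_acquisition` evaluates the Stejskal–Tanner forward model on a
  dense scheme (default 90 directions + 1 b=0, b = 1000 s/mm²) and adds
  Rician noise: `S' = sqrt((S + n1)² + n2²)` with `n1, n2 ~ N(0, σ²)` and
  `σ = mean(b0 inside brain) / SNR`.

Realism is deliberately limited to what the enhancement task needs: smooth
piecewise-constant anatomy, correct signal physics, correct noise statistics.
There is no CSF compartment, no partial-volume mixing beyond mask edges, no
susceptibility or motion artefacts, and tracts do not cross.

## 5. Network

`network.UNet3D` is a 3-D encoder/decoder implemented in pure NumPy
(`layers.py` provides Conv3d, ConvTranspose3d, MaxPool3d, InstanceNorm3d,
ReLU and Adam with hand-written backprop, each verified against numerical
gradients in the tests). Architecture:

- Input: 8 channels — T1, b=0, six diffusion-weighted volumes.
- Output: 6 channels — the tensor coefficients.
- Four resolution levels with reference widths (32, 64, 128, 256), scaled by
  `width_scale`; 2× max-pool downsampling and transposed-conv upsampling with
  skip connections; dilation 2 in the bottleneck. Inputs must be divisible
  by `DOWN_FACTOR = 16`.
- Instance normalisation after each convolution (identity on 1³ spatial
  volumes, where per-instance statistics are undefined); convolutions carry
  no bias when followed by normalisation.

Tests and the acceptance script run the network at `width_scale = 1/8`
(widths 4/8/16/32) so that training fits a single-CPU minute budget; the
architecture is identical at full width.

## 6. Training pipeline

- **Inputs** are z-scored per image over the brain mask
  (`pipeline.normalize_inputs`).
- **Targets** are the six coefficients of the dense-scheme fit, z-scored per
  coefficient over white-matter voxels pooled across the training subjects;
  the statistics are stored in the checkpoint and inverted at prediction
  time.
- **Patches**: volumes are cut into overlapping cubes
  (`plan_patches(shape, patch, overlap)`; stride = patch − overlap, with the
  last origin along each axis clamped so the final patch ends exactly at the
  (padded) boundary). For a 145×174×145 grid with 64³ patches and 32-voxel
  overlap this yields the fixed 80-patch plan checked in the acceptance
  tests. Patches whose white-matter fraction is too low are discarded from
  training. At inference, overlapping predictions are averaged unweighted and
  the result cropped back to the original grid — an exact inverse when the
  predictor is exact, which the tests verify.
- **Loss**: L1 on the six coefficients restricted to white-matter voxels, so
  background never influences the weights.
- **Optimiser**: Adam, with seeded initialisation and shuffling for full
  determinism.

## 7. Evaluation and statistics

`evaluation` provides MAE, a 3-D Gaussian-window SSIM (scikit-image), and
normalised cross-correlation, all restricted to a mask, plus per-region
aggregation (`region_report`).

`compare_groups` is a small two-sample harness: a Shapiro–Wilk gate at 0.05
selects between paired t / Wilcoxon signed-rank (paired) or independent t /
Mann–Whitney U (unpaired); `force_normal` overrides the gate. Significance
uses Bonferroni-corrected alpha `alpha / n_comparisons` (default 0.01 / 20 =
0.0005). Identical paired samples short-circuit to p = 1.

`experiments.run_generalisation` builds the input-variant sets used to probe
a trained predictor:

- `LAR_KS` — the deterministic Kennard–Stone 6-subset (1 input);
- `LAR_Random` — 10 random-first-pick subsets;
- `LAR_Shuffled` — 5 channel-order permutations of each random subset (50);
- `LAR_B0` — each random subset with one direction replaced by the b=0
  volume (10).

Hypotheses: H1 (sampling scheme does not change error), H2 (channel order
does not change error), H3 (replacing a direction with b=0 degrades the
prediction). Note that H2 as a Random-vs-Shuffled location test cannot detect
order sensitivity in general — the identity ordering is just one of 720
permutations, so both groups are draws from the same error distribution even
for an order-sensitive predictor. Order dependence is therefore also exposed
at table level: per-input errors of shuffled variants move relative to their
parent inputs if and only if the predictor depends on channel order.

## 8. Numerical choices

- Log-linear OLS (not weighted or nonlinear) for the tensor fit: exact on
  noiseless data, standard, and fast enough to fit every voxel of every
  phantom in the test budget.
- `pinv`-based solving tolerates the exactly determined 7×7 minimal case and
  the overdetermined dense case uniformly.
- Noise-free recovery is validated to 1e-8 relative error; closed-form FA
  values to 1e-12.
- All stochastic components (phantom anatomy, noise, network init, batch
  shuffling, random subsets) take explicit seeds; every test and the
  acceptance script are deterministic.

## 9. Limitations

- The phantom is far simpler than real brain data; measured error reductions
  quantify the pipeline's correctness, not expected clinical performance.
- The NumPy network is CPU-only and slow at full width; desk-scale runs use
  `width_scale = 1/8` and small grids.
- The tensor model itself cannot represent crossing fibres; the enhancement
  inherits that ceiling.
- SSIM on masked, near-constant regions is sensitive to the data range; the
  implementation rejects constant references instead of guessing.
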