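# dtienhance

Deep-learning enhancement of diffusion tensor imaging (DTI) from minimal
six-direction acquisitions.

## The problem

A diffusion tensor has six free coefficients, so together with the unknown
baseline signal it can be fitted from a single b=0 volume plus six diffusion
directions — a scan of a couple of minutes instead of the ten-plus minutes a
dense 60–90-direction protocol needs. The catch is noise: with only six
measurements the fit has no redundancy, and derived scalar maps such as
fractional anisotropy (FA) come out biased and noisy compared with a dense
fit of the same subject.

`dtienhance` implements the full pipeline for closing that gap with a 3-D
convolutional encoder/decoder network:

- **`gradients`** — FSL bval/bvec I/O and maximin (Kennard–Stone)
  subsampling of a dense direction scheme on the antipodally identified
  hemisphere;
- **`tensor`** — log-linear least-squares tensor fitting, the forward
  Stejskal–Tanner signal model, and FA/MD/AD/RD scalar maps;
- **`phantom`** — a seeded synthetic brain phantom (tracts with prescribed
  FA/MD in an isotropic background, a T1-like channel, Rician noise) used
  for training, evaluation and all tests;
- **`network`** — a pure-NumPy 3-D U-Net-style network (hand-written
  backprop, Adam) taking 8 input channels (T1, b0, six diffusion volumes)
  to the 6 tensor coefficients;
- **`pipeline`** — patch extraction with overlap-averaged reassembly,
  normalization, white-matter-masked L1 training, checkpointing, inference;
- **`evaluation`** — masked MAE/SSIM/NCC, per-region reports, and a
  normality-gated statistical comparison harness with Bonferroni
  correction;
- **`experiments`** — the FA-versus-direction-count curve and a
  generalisation suite probing trained models with resampled, shuffled and
  b0-corrupted input sets.

See [docs/methods.md](docs/methods.md) for the model and the design
decisions.

## Worked example

Simulate a subject, fit the dense reference, then fit the minimal
six-direction subset chosen by Kennard–Stone sampling:

```python
import numpy as np
from dtienhance.gradients import kennard_stone_sample, subset_scheme
from dtienhance.phantom import PhantomSpec, build_phantom, simulate_acquisition
from dtienhance.tensor import fit_tensor, scalar_maps

phantom = build_phantom(PhantomSpec(grid_shape=(32, 32, 32), seed=0))
dwi = simulate_acquisition(phantom, snr=20.0, seed=42)   # (32, 32, 32, 91)

ks = kennard_stone_sample(phantom.scheme, 6)
print("KS subset indices:", ks.indices)

idx = list(np.flatnonzero(phantom.scheme.b0_flags)) + list(ks.indices)
minimal = subset_scheme(phantom.scheme, ks)

fa_dense = scalar_maps(fit_tensor(dwi, phantom.scheme, mask=phantom.brain_mask)).fa
fa_min = scalar_maps(fit_tensor(dwi[..., idx], minimal, mask=phantom.brain_mask)).fa

wm = phantom.wm_mask
print(f"mean WM FA, 90 directions: {fa_dense[wm].mean():.4f}")
print(f"mean WM FA,  6 directions: {fa_min[wm].mean():.4f}")
print(f"WM FA MAE, 6 vs 90:        {np.abs(fa_min - fa_dense)[wm].mean():.4f}")
```

Output:

```
KS subset indices: (12, 31, 82, 63, 75, 32)
mean WM FA, 90 directions: 0.6959
mean WM FA,  6 directions: 0.7203
WM FA MAE, 6 vs 90:        0.0656
```

The six-direction fit overestimates white-matter FA and carries a mean
absolute FA error of 0.066 against the dense reference. Training the
desk-scale network (width scale 1/8, ≈206k parameters, 500 Adam steps,
about two minutes on one CPU) on four phantom subjects and predicting the
held-out fifth reduces that error by more than a third:

```
raw 6-direction WM FA MAE:   0.0656
enhanced WM FA MAE:          0.0366   (44.2 % lower)
```

The error of the raw fit also falls with direction count, reproducing the
expected angular-resolution curve (mean WM |FA(k) − FA(90)| on noisy 48³
phantoms at SNR 20):

| directions k | 6 | 12 | 30 | 90 |
|---|---|---|---|---|
| FA error | 0.0665 | 0.0398 | 0.0232 | 0.0 |

## Command line

The `dtienhance` CLI covers the same pipeline end to end:

```
dtienhance simulate   --spec spec.yaml --out subj/ --snr 20 --seed 0
dtienhance validate   subj/
dtienhance sample-dirs subj/bvals subj/bvecs -k 6 --out ks6/
dtienhance fit-dti    subj/ --out fit/
dtienhance train      --config train.yaml --out ckpt/
dtienhance predict    subj/ --ckpt ckpt/checkpoint.npz --out pred/
dtienhance experiment --mode fa-curve --manifest manifest.yaml --out curve/
dtienhance stats      --table results.csv --out stats.json
```

## Reproduction

All numbers above come from deterministic seeded runs and are regenerated
by:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which runs the whole pipeline (tensor recovery, sampling properties, the
FA-vs-directions curve, desk-scale training with a held-out subject, the
patch-grid constants, and the statistics-harness calibration) in about two
minutes on one CPU and writes every quantity quoted here to the JSON file.

The test suite, including property-based tests and one acceptance test per
shipped guarantee, runs with:

```
pytest -q
```

(≈ 2.5 minutes on one CPU; the single slow training test is marked `slow`
and can be deselected with `-m "not slow"`.)
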