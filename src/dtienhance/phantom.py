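"""Synthetic single-shell acquisitions with known ground-truth tensors.

The phantom emulates a preprocessed single-shell (b=1000 s/mm^2,
90-direction) brain acquisition at desk scale: tract-like anisotropic
regions (slabs, tubes, crossings) embedded in an isotropic background
inside a spherical brain, a surrogate piecewise-constant T1, a constant
b0 intensity, and Rician noise on the simulated magnitude signals.
Every downstream stage (subsampling, fitting, training, evaluation) can
be tested against the phantom's exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .gradients import GradientScheme
from .tensor import DiffusionTensorField, forward_signal, tensor_from_eigen

__all__ = [
    "TractSpec",
    "PhantomSpec",
    "Phantom",
    "PhantomSpecError",
    "make_dense_scheme",
    "axially_symmetric_eigenvalues",
    "build_phantom",
    "simulate_acquisition",
    "write_subject",
]


class PhantomSpecError(ValueError):
    """Infeasible or inconsistent phantom specification."""


@dataclass
class TractSpec:
    """One synthetic tract: geometry, orientation and target diffusion.

    geometry: "slab" (axis-aligned plate), "tube" (cylinder through the
    volume center) or "crossing" (two tubes; ``direction`` then holds two
    unit vectors).  ``fa``/``md`` are the target fractional anisotropy
    (dimensionless, < 1) and mean diffusivity (mm^2/s) of the tract.
    """

    geometry: str
    direction: Tuple
    fa: float
    md: float
    center: Optional[Tuple[float, float, float]] = None
    radius: float = 0.12  # fraction of grid extent (tube radius / slab half-thickness)

    def __post_init__(self):
        # canonical plain-float tuples so specs compare equal after a
        # YAML round trip
        def tup(x):
            if x is None:
                return None
            x = np.asarray(x, dtype=float)
            if x.ndim == 1:
                return tuple(float(v) for v in x)
            return tuple(tuple(float(v) for v in row) for row in x)

        self.direction = tup(self.direction)
        self.center = tup(self.center)
        self.fa = float(self.fa)
        self.md = float(self.md)
        self.radius = float(self.radius)

    def directions(self) -> List[np.ndarray]:
        d = np.asarray(self.direction, dtype=float)
        if d.ndim == 1:
            d = d[None, :]
        return [row / np.linalg.norm(row) for row in d]


def _default_tracts() -> List[TractSpec]:
    # two crossing tubes and one slab, the desk-scale default geometry;
    # fiber directions are oblique so that (like the mix of commissural,
    # projection and association tracts in real WM) every one of the six
    # tensor coefficients carries orientation signal
    s2, s3 = 1.0 / np.sqrt(2.0), 1.0 / np.sqrt(3.0)
    return [
        TractSpec(
            geometry="crossing",
            direction=((s2, s2, 0.0), (s3, -s3, s3)),
            fa=0.8,
            md=0.8e-3,
            center=(0.5, 0.5, 0.42),
            radius=0.10,
        ),
        TractSpec(
            geometry="slab",
            direction=(0.0, s2, s2),
            fa=0.6,
            md=0.8e-3,
            center=(0.5, 0.5, 0.72),
            radius=0.06,
        ),
    ]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject."""

    grid_shape: Tuple[int, int, int] = (48, 48, 48)
    n_directions: int = 90
    bval: float = 1000.0
    n_b0: int = 1
    tract_specs: List[TractSpec] = field(default_factory=_default_tracts)
    background_md: float = 0.7e-3  # roughly grey-matter-like isotropic diffusivity
    snr: float = 20.0
    seed: int = 0
    # all subjects of a study share one acquisition protocol, so the
    # gradient scheme is seeded independently of the subject seed
    scheme_seed: int = 0

    def __post_init__(self):
        if min(self.grid_shape) < 16:
            raise PhantomSpecError("grid dims must be >= 16")
        if self.snr <= 0:
            raise PhantomSpecError("snr must be > 0")
        for t in self.tract_specs:
            if not (0.0 <= t.fa < 1.0):
                raise PhantomSpecError(f"target FA {t.fa} outside [0, 1)")

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            return obj

        Path(path).write_text(yaml.safe_dump(plain(asdict(self)), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["tract_specs"] = [TractSpec(**t) for t in d.get("tract_specs", [])]
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class Phantom:
    """Ground-truth tensor field plus masks and surrogate structural data."""

    gt_tensor: DiffusionTensorField
    wm_mask: np.ndarray
    gm_mask: np.ndarray
    brain_mask: np.ndarray
    t1: np.ndarray
    s0: np.ndarray
    scheme: GradientScheme
    spec: PhantomSpec
    tract_labels: np.ndarray  # int volume, 0 = background, i = tract_specs[i-1]


def make_dense_scheme(
    n: int = 90, bval: float = 1000.0, n_b0: int = 1, seed: int = 0
) -> GradientScheme:
    """Approximately uniform hemisphere directions via a Fibonacci
    lattice, randomly rotated by the seed, preceded by ``n_b0`` b0s."""
    if n < 6:
        raise ValueError("need at least 6 directions")
    if n_b0 < 1:
        raise ValueError("need at least one b0")
    i = np.arange(n)
    z = (i + 0.5) / n  # upper hemisphere only
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z * z)
    vecs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # seeded random rotation so different seeds give distinct (but equally
    # uniform) schemes
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    vecs = vecs @ Q.T
    bvals = np.concatenate([np.zeros(n_b0), np.full(n, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), vecs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def axially_symmetric_eigenvalues(fa: float, md: float) -> Tuple[float, float]:
    """Solve (l1, l2=l3) from target FA and MD for a prolate tensor.

    With l1 = MD(1+2d), l2 = l3 = MD(1-d) the FA formula reduces to
    FA = 3d / sqrt(3 + 6 d^2), inverted in closed form as
    d = FA / sqrt(3 - 2 FA^2).
    """
    if not (0.0 <= fa < 1.0):
        raise PhantomSpecError(f"FA {fa} outside [0, 1)")
    if md <= 0:
        raise PhantomSpecError("MD must be > 0")
    d = fa / np.sqrt(3.0 - 2.0 * fa * fa)
    lam1 = md * (1.0 + 2.0 * d)
    lam2 = md * (1.0 - d)
    if lam2 < 0:
        raise PhantomSpecError(f"(FA={fa}, MD={md}) requires a negative eigenvalue")
    return float(lam1), float(lam2)


def _region_masks(spec: PhantomSpec):
    """Voxel masks per tract, with per-voxel dominant-direction bookkeeping
    for crossings.  Returns (labels, direction volume) where labels is an
    int volume (0 background) and directions holds the locally dominant
    principal axis per tract voxel."""
    shape = np.array(spec.grid_shape)
    zyx = np.stack(
        np.meshgrid(*[np.arange(s) for s in spec.grid_shape], indexing="ij"), axis=-1
    ).astype(float)
    frac = zyx / (shape - 1.0)  # 0..1 coordinates
    extent = float(np.mean(shape))

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    dirs = np.zeros(spec.grid_shape + (3,))

    for ti, tract in enumerate(spec.tract_specs, start=1):
        center = np.array(tract.center if tract.center is not None else (0.5, 0.5, 0.5))
        rel = (frac - center) * (shape - 1.0) / extent  # roughly isotropic coords
        if tract.geometry == "slab":
            axis = tract.directions()[0]
            # slab normal to the z axis of the local frame; principal
            # diffusion direction lies in-plane along `direction` x z
            normal = np.array([0.0, 0.0, 1.0])
            inside = np.abs(rel @ normal) <= tract.radius
            principal = axis
            sel = inside & (labels == 0)
            labels[sel] = ti
            dirs[sel] = principal
        elif tract.geometry in ("tube", "crossing"):
            axes = tract.directions()
            if tract.geometry == "tube":
                axes = axes[:1]
            # distance of each voxel to each tube axis (through `center`)
            dists = []
            for ax in axes:
                proj = rel - np.einsum("...i,i->...", rel, ax)[..., None] * ax
                dists.append(np.linalg.norm(proj, axis=-1))
            dists = np.stack(dists, axis=0)  # (n_axes, X, Y, Z)
            inside_any = np.any(dists <= tract.radius, axis=0)
            dominant = np.argmin(dists, axis=0)  # nearest axis wins in crossings
            sel = inside_any & (labels == 0)
            labels[sel] = ti
            for ai, ax in enumerate(axes):
                dirs[sel & (dominant == ai)] = ax
        else:
            raise PhantomSpecError(f"unknown geometry {tract.geometry!r}")
    return labels, dirs


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Construct ground-truth tensors, masks and surrogate T1/b0.

    The subject seed drives the anatomy (small jitter of tract positions,
    T1 texture); the acquisition protocol is shared across subjects via
    ``scheme_seed``.
    """
    rng_anat = np.random.default_rng(spec.seed)
    jittered = []
    for t in spec.tract_specs:
        c = np.array(t.center if t.center is not None else (0.5, 0.5, 0.5))
        c = c + rng_anat.uniform(-0.03, 0.03, 3)
        jittered.append(
            TractSpec(geometry=t.geometry, direction=t.direction, fa=t.fa,
                      md=t.md, center=tuple(c), radius=t.radius)
        )
    spec_j = PhantomSpec(
        grid_shape=spec.grid_shape, n_directions=spec.n_directions,
        bval=spec.bval, n_b0=spec.n_b0, tract_specs=jittered,
        background_md=spec.background_md, snr=spec.snr, seed=spec.seed,
        scheme_seed=spec.scheme_seed,
    )
    shape = spec.grid_shape
    center = (np.array(shape) - 1.0) / 2.0
    zyx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float)
    radius = 0.46 * float(np.mean(shape))
    brain_mask = np.linalg.norm(zyx - center, axis=-1) <= radius

    labels, dirs = _region_masks(spec_j)
    labels[~brain_mask] = 0
    wm_mask = labels > 0
    gm_mask = brain_mask & ~wm_mask
    if not wm_mask.any() or not gm_mask.any():
        raise PhantomSpecError("degenerate phantom: empty WM or GM mask")

    coeffs = np.zeros((6,) + tuple(shape))
    iso = spec.background_md * np.array([1.0, 0.0, 0.0, 1.0, 0.0, 1.0])
    coeffs[:, gm_mask] = iso[:, None]
    for ti, tract in enumerate(spec.tract_specs, start=1):
        lam1, lam2 = axially_symmetric_eigenvalues(tract.fa, tract.md)
        sel = labels == ti
        if not sel.any():
            continue
        vox_dirs = dirs[sel]
        uniq, inv = np.unique(np.round(vox_dirs, 12), axis=0, return_inverse=True)
        six = np.stack(
            [tensor_from_eigen((lam1, lam2, lam2), u) for u in uniq], axis=0
        )
        coeffs[:, sel] = six[inv].T

    gt = DiffusionTensorField(coeffs=coeffs, mask=brain_mask)

    rng = np.random.default_rng(spec.seed)
    t1 = np.where(wm_mask, 0.7, np.where(gm_mask, 1.0, 0.05))
    t1 = gaussian_filter(t1, sigma=1.0)
    t1 = t1 * (1.0 + 0.01 * rng.standard_normal(shape))

    s0 = np.where(brain_mask, 1000.0, 0.0)

    scheme = make_dense_scheme(
        n=spec.n_directions, bval=spec.bval, n_b0=spec.n_b0, seed=spec.scheme_seed
    )
    return Phantom(
        gt_tensor=gt,
        wm_mask=wm_mask,
        gm_mask=gm_mask,
        brain_mask=brain_mask,
        t1=t1,
        s0=s0,
        scheme=scheme,
        spec=spec,
        tract_labels=labels,
    )


def simulate_acquisition(
    phantom: Phantom,
    scheme: Optional[GradientScheme] = None,
    snr: Optional[float] = None,
    seed: int = 0,
) -> np.ndarray:
    """Noisy magnitude signals, shape (X, Y, Z, N).

    Rician noise: S_noisy = sqrt((S + n1)^2 + n2^2) with n1, n2 drawn
    i.i.d. Normal(0, sigma^2), sigma = mean(s0 inside brain) / snr.
    ``snr=inf`` (or None with spec.snr=inf) returns the noiseless signal.
    """
    scheme = scheme if scheme is not None else phantom.scheme
    snr = float(snr if snr is not None else phantom.spec.snr)
    if snr <= 0:
        raise ValueError("snr must be > 0")
    clean = forward_signal(phantom.gt_tensor, scheme, phantom.s0)
    if not np.isfinite(snr):
        return clean
    sigma = float(phantom.s0[phantom.brain_mask].mean()) / snr
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, clean.shape)
    n2 = rng.normal(0.0, sigma, clean.shape)
    return np.sqrt((clean + n1) ** 2 + n2**2)


def write_subject(phantom: Phantom, out_dir, snr: Optional[float] = None,
                  seed: int = 0) -> Path:
    """Write a complete fake-subject directory (NIfTI + bval/bvec + spec)."""
    # imported here to keep phantom construction free of file I/O deps
    from . import io as io_mod
    from .gradients import save_fsl_gradients

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dwi = simulate_acquisition(phantom, snr=snr, seed=seed)
    aff = phantom.gt_tensor.affine
    io_mod.write_volume(out / "dwi.nii.gz", dwi, aff)
    b0_idx = int(np.flatnonzero(phantom.scheme.b0_flags)[0])
    io_mod.write_volume(out / "b0.nii.gz", dwi[..., b0_idx], aff)
    io_mod.write_volume(out / "t1.nii.gz", phantom.t1, aff)
    io_mod.write_volume(out / "wm_mask.nii.gz", phantom.wm_mask.astype(np.uint8), aff)
    io_mod.write_volume(out / "gm_mask.nii.gz", phantom.gm_mask.astype(np.uint8), aff)
    io_mod.write_volume(
        out / "brain_mask.nii.gz", phantom.brain_mask.astype(np.uint8), aff
    )
    io_mod.write_tensor(out / "gt_tensor.nii.gz", phantom.gt_tensor)
    save_fsl_gradients(phantom.scheme, out / "dwi.bval", out / "dwi.bvec")
    phantom.spec.to_yaml(out / "spec.yaml")
    return out
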