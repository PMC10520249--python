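"""Diffusion tensor forward model, log-linear fitting and scalar maps.

The single-tensor model relates the diffusion-weighted signal to a
symmetric 3x3 tensor D via the monoexponential (Stejskal-Tanner) decay

    S_i = S0 * exp(-b_i * g_i^T D g_i),

which is linear in the 6 unique coefficients (Dxx, Dxy, Dxz, Dyy, Dyz,
Dzz) after taking logs.  Fitting is ordinary least squares on the
log-signals (the DTIFIT default behaviour); weighted least squares is
available behind a flag.  Scalar maps use the standard eigenvalue
definitions: MD = (l1+l2+l3)/3, AD = l1, RD = (l2+l3)/2 and
FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gradients import GradientScheme

__all__ = [
    "DiffusionTensorField",
    "ScalarMaps",
    "DegenerateSchemeError",
    "design_matrix",
    "forward_signal",
    "fit_tensor",
    "scalar_maps",
    "eigenvalues",
    "tensor_from_eigen",
]

logger = logging.getLogger(__name__)

#: fixed coefficient ordering of the 6 unique tensor components
COEFF_NAMES = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

# index pairs of each coefficient inside the symmetric 3x3 matrix
_IJ = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


class DegenerateSchemeError(ValueError):
    """Gradient scheme cannot determine a unique tensor (rank < 7)."""


@dataclass
class DiffusionTensorField:
    """Per-voxel symmetric tensor volume.

    coeffs has shape (6, X, Y, Z) ordered (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)
    in mm^2/s; outside ``mask`` all coefficients are zero.
    """

    coeffs: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 4 or self.coeffs.shape[0] != 6:
            raise ValueError(f"coeffs must be (6, X, Y, Z), got {self.coeffs.shape}")
        if self.mask is None:
            self.mask = np.ones(self.coeffs.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.coeffs.shape[1:]:
            raise ValueError("mask shape does not match tensor grid")
        self.coeffs = self.coeffs * self.mask  # zero outside the mask

    @property
    def shape(self):
        return self.coeffs.shape[1:]

    def as_matrices(self) -> np.ndarray:
        """Expand to (..., 3, 3) symmetric matrices."""
        out = np.zeros(self.shape + (3, 3))
        for c, (i, j) in enumerate(_IJ):
            out[..., i, j] = self.coeffs[c]
            out[..., j, i] = self.coeffs[c]
        return out


@dataclass
class ScalarMaps:
    """FA (dimensionless) and MD/AD/RD (mm^2/s) volumes on the tensor grid."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray

    def as_dict(self):
        return {"fa": self.fa, "md": self.md, "ad": self.ad, "rd": self.rd}


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Log-linear system matrix, one row per volume, 7 columns.

    Row i is (-b gx^2, -2b gx gy, -2b gx gz, -b gy^2, -2b gy gz, -b gz^2, 1)
    so that ``ln S = row . (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz, ln S0)``.
    b0 rows are (0, ..., 0, 1).
    """
    b = np.where(scheme.b0_flags, 0.0, scheme.bvals)
    gx, gy, gz = scheme.bvecs.T
    X = np.column_stack(
        [
            -b * gx * gx,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -b * gy * gy,
            -2 * b * gy * gz,
            -b * gz * gz,
            np.ones_like(b),
        ]
    )
    # zero out the direction part of b0 rows exactly
    X[scheme.b0_flags, :6] = 0.0
    return X


def forward_signal(
    tensor: DiffusionTensorField, scheme: GradientScheme, s0: np.ndarray
) -> np.ndarray:
    """Noiseless monoexponential signals, shape (X, Y, Z, N).

    b0 volumes return S0; voxels outside the tensor mask return 0.
    """
    if np.any(scheme.bvals < 0):
        raise ValueError("negative b-value")
    s0 = np.asarray(s0, dtype=float)
    if s0.shape != tensor.shape:
        raise ValueError("s0 grid does not match tensor grid")
    A = design_matrix(scheme)[:, :6]  # (N, 6)
    flat = tensor.coeffs.reshape(6, -1)  # (6, V)
    expo = A @ flat  # (N, V) = -b g^T D g
    sig = s0.reshape(1, -1) * np.exp(expo)
    sig = sig.T.reshape(tensor.shape + (len(scheme),))
    sig[~tensor.mask] = 0.0
    return sig


def fit_tensor(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: Optional[np.ndarray] = None,
    affine: Optional[np.ndarray] = None,
    weighted: bool = False,
) -> DiffusionTensorField:
    """Voxelwise least-squares tensor fit on log-signals.

    Parameters
    ----------
    dwi : (X, Y, Z, N) array
        Diffusion-weighted volumes, one per scheme entry.
    scheme : GradientScheme
        Must span a rank-7 design (>= 1 b0 and >= 6 non-coplanar
        directions).
    mask : (X, Y, Z) bool array, optional
        Fit domain; outside it coefficients are zero.
    weighted : bool
        When True, a second weighted pass (weights = fitted signals)
        refines the OLS solution.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[3] != len(scheme):
        raise ValueError(
            f"dwi shape {dwi.shape} does not match scheme length {len(scheme)}"
        )
    if not np.any(scheme.b0_flags):
        raise DegenerateSchemeError("scheme has no b0 volume")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise DegenerateSchemeError("design matrix rank < 7; tensor not identifiable")

    grid = dwi.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    sig = dwi[mask]  # (M, N)
    coeffs = np.zeros((6,) + grid)
    if sig.size:
        s0_ref = float(np.max(sig[:, scheme.b0_flags], initial=0.0))
        eps = 1e-6 * s0_ref if s0_ref > 0 else 1e-12
        dead = np.all(sig <= 0, axis=1)
        if np.any(dead):
            logger.warning("%d all-zero voxel(s) inside mask: fit skipped", dead.sum())
        # floor only non-positive samples: any positive signal is a valid
        # log-domain measurement and must pass through unchanged
        logs = np.log(np.where(sig > 0, sig, eps))
        beta, *_ = np.linalg.lstsq(X, logs.T, rcond=None)  # (7, M)
        if weighted:
            # one WLS refinement with weights from the current prediction
            w = np.exp(X @ beta)  # (N, M) predicted signals
            for m in range(beta.shape[1]):
                Wm = w[:, m]
                Xw = X * Wm[:, None]
                beta[:, m] = np.linalg.lstsq(Xw, Wm * logs[m], rcond=None)[0]
        beta[:, dead] = 0.0
        out = np.zeros((mask.sum(), 6))
        out[:] = beta[:6].T
        full = np.zeros(grid + (6,))
        full[mask] = out
        coeffs = np.moveaxis(full, -1, 0)
    return DiffusionTensorField(
        coeffs=coeffs,
        affine=np.eye(4) if affine is None else affine,
        mask=mask,
    )


def eigenvalues(tensor: DiffusionTensorField) -> np.ndarray:
    """Sorted (descending) eigenvalues, shape (X, Y, Z, 3)."""
    mats = tensor.as_matrices()
    if not np.all(np.isfinite(mats[tensor.mask])):
        raise ValueError("non-finite tensor coefficients inside mask")
    evals = np.linalg.eigvalsh(mats)  # ascending
    return evals[..., ::-1]


def _fa_from_eigenvalues(lam: np.ndarray) -> np.ndarray:
    md = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - md, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)  # FA of the zero tensor is 0 by convention
    return np.clip(fa, 0.0, 1.0)


def scalar_maps(tensor: DiffusionTensorField) -> ScalarMaps:
    """FA/MD/AD/RD maps; eigenvalues are clamped to >= 0 first."""
    lam = np.clip(eigenvalues(tensor), 0.0, None)
    fa = _fa_from_eigenvalues(lam)
    ad = lam[..., 0]
    rd = 0.5 * (lam[..., 1] + lam[..., 2])
    md = (ad + 2.0 * rd) / 3.0
    m = tensor.mask
    return ScalarMaps(fa=fa * m, md=md * m, ad=ad * m, rd=rd * m)


def tensor_from_eigen(evals, principal_axis) -> np.ndarray:
    """6-coefficient tensor with given eigenvalues (l1, l2, l3) and
    principal eigenvector; the two minor axes are any orthonormal
    completion (axially symmetric use only cares about l2 == l3)."""
    e1 = np.asarray(principal_axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    D = R @ np.diag(evals) @ R.T
    return np.array([D[0, 0], D[0, 1], D[0, 2], D[1, 1], D[1, 2], D[2, 2]])
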