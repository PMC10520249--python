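"""NIfTI and subject-bundle I/O.

Volumes travel as NIfTI-1 (.nii/.nii.gz) via nibabel with the affine
preserved; tensor fields are stored with the coefficient axis as the
4th NIfTI dimension plus a JSON sidecar naming the coefficient order.
Co-registration is a precondition: bundles are validated for matching
grids and affines, never resampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import nibabel as nib
import numpy as np

from .gradients import GradientScheme, load_fsl_gradients
from .tensor import COEFF_NAMES, DiffusionTensorField

__all__ = [
    "BundleValidationError",
    "SubjectBundle",
    "read_volume",
    "write_volume",
    "read_tensor",
    "write_tensor",
    "validate_bundle",
]

_AFFINE_TOL = 1e-4


class BundleValidationError(ValueError):
    """One or more subject-bundle invariants failed; carries the full list."""

    def __init__(self, errors: List[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def read_volume(path) -> Tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_volume(path, data: np.ndarray, affine: Optional[np.ndarray] = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def write_tensor(path, tensor: DiffusionTensorField) -> None:
    """Coefficient axis moved last for the NIfTI file; JSON sidecar
    records the coefficient order."""
    data = np.moveaxis(tensor.coeffs, 0, -1)
    write_volume(path, data, tensor.affine)
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    Path(f"{sidecar}.json").write_text(
        json.dumps({"coefficients": list(COEFF_NAMES)}, indent=2)
    )


def read_tensor(path, mask: Optional[np.ndarray] = None) -> DiffusionTensorField:
    data, affine = read_volume(path)
    if data.ndim != 4 or data.shape[3] != 6:
        raise ValueError(f"tensor file must be (X, Y, Z, 6), got {data.shape}")
    return DiffusionTensorField(
        coeffs=np.moveaxis(data, -1, 0), affine=affine, mask=mask
    )


@dataclass
class SubjectBundle:
    """Resolved and validated paths + grid metadata for one subject."""

    t1: Path
    b0: Path
    dwi: Path
    bval: Path
    bvec: Path
    brain_mask: Path
    wm_mask: Optional[Path] = None
    gm_mask: Optional[Path] = None
    gt_tensor: Optional[Path] = None
    grid_shape: Optional[Tuple[int, int, int]] = None
    affine: Optional[np.ndarray] = None
    scheme: Optional[GradientScheme] = None


def validate_bundle(
    t1,
    b0,
    dwi,
    bval,
    bvec,
    brain_mask,
    wm_mask=None,
    gm_mask=None,
    gt_tensor=None,
) -> SubjectBundle:
    """Check all bundle invariants; raises BundleValidationError listing
    every violation (no partial bundle is returned)."""
    errors: List[str] = []
    roles = {
        "t1": t1, "b0": b0, "dwi": dwi, "bval": bval, "bvec": bvec,
        "brain_mask": brain_mask, "wm_mask": wm_mask, "gm_mask": gm_mask,
        "gt_tensor": gt_tensor,
    }
    for role, p in roles.items():
        if p is not None and not Path(p).exists():
            errors.append(f"missing {role}: {p}")
    if errors:
        raise BundleValidationError(errors)

    vols: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for role in ("t1", "b0", "dwi", "brain_mask", "wm_mask", "gm_mask", "gt_tensor"):
        p = roles[role]
        if p is None:
            continue
        try:
            vols[role] = read_volume(p)
        except Exception as exc:  # malformed header etc.
            errors.append(f"cannot read {role}: {exc}")
    scheme = None
    try:
        scheme = load_fsl_gradients(roles["bval"], roles["bvec"])
    except Exception as exc:
        errors.append(f"gradient table: {exc}")
    if errors:
        raise BundleValidationError(errors)

    grid = vols["t1"][0].shape[:3]
    affine = vols["t1"][1]
    for role, (data, aff) in vols.items():
        if data.shape[:3] != grid:
            errors.append(f"grid mismatch: {role} {data.shape[:3]} vs t1 {grid}")
        if np.max(np.abs(aff - affine)) > _AFFINE_TOL:
            errors.append(f"affine mismatch between t1 and {role}")
    dwi_data = vols["dwi"][0]
    if dwi_data.ndim != 4:
        errors.append(f"dwi must be 4D, got {dwi_data.ndim}D")
    elif scheme is not None and dwi_data.shape[3] != len(scheme):
        errors.append(
            f"dwi has {dwi_data.shape[3]} volumes but gradient table has "
            f"{len(scheme)} entries"
        )
    if roles["gt_tensor"] is not None and vols["gt_tensor"][0].shape[3:] != (6,):
        errors.append("gt_tensor must hold 6 coefficient volumes")
    if errors:
        raise BundleValidationError(errors)

    return SubjectBundle(
        t1=Path(t1), b0=Path(b0), dwi=Path(dwi), bval=Path(bval), bvec=Path(bvec),
        brain_mask=Path(brain_mask),
        wm_mask=Path(wm_mask) if wm_mask else None,
        gm_mask=Path(gm_mask) if gm_mask else None,
        gt_tensor=Path(gt_tensor) if gt_tensor else None,
        grid_shape=grid, affine=affine, scheme=scheme,
    )
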