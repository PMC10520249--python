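"""Gradient tables and evenly distributed direction subsampling.

Diffusion gradient directions (bvecs) live on the unit sphere, but a
gradient and its negation encode the same measurement, so distances
between directions are computed after antipodal identification.  Minimal
"evenly distributed" subsets are selected with the Kennard-Stone (KS)
greedy maximin algorithm, or its randomized variant in which only the
first pick is random and the remaining picks follow the KS rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np

__all__ = [
    "GradientScheme",
    "DirectionSample",
    "GradientFormatError",
    "GradientValidationError",
    "load_fsl_gradients",
    "save_fsl_gradients",
    "hemisphere_distance",
    "hemisphere_distance_matrix",
    "kennard_stone_sample",
    "random_ks_sample",
    "subset_scheme",
]

#: b-values below this (s/mm^2) are treated as unweighted (b0) volumes.
DEFAULT_B0_THRESHOLD = 50.0

_UNIT_TOL = 1e-4


class GradientFormatError(ValueError):
    """Malformed bval/bvec text table."""


class GradientValidationError(ValueError):
    """Gradient table violates a physical invariant (e.g. non-unit bvec)."""


@dataclass(frozen=True)
class GradientScheme:
    """b-values and unit gradient directions of one acquisition.

    Parameters
    ----------
    bvals : (N,) array
        Diffusion weightings in s/mm^2.
    bvecs : (N, 3) array
        Unit direction per volume (arbitrary for b0 volumes).
    b0_threshold : float
        Volumes with ``bval < b0_threshold`` are flagged as b0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).reshape(-1)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientValidationError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise GradientValidationError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) differ in length"
            )
        if bvals.shape[0] < 1:
            raise GradientValidationError("empty gradient scheme")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        norms = np.linalg.norm(bvecs, axis=1)
        bad = (~self.b0_flags) & (np.abs(norms - 1.0) > _UNIT_TOL)
        if np.any(bad):
            raise GradientValidationError(
                f"non-unit bvec(s) at volume(s) {np.flatnonzero(bad).tolist()} "
                f"(norms {norms[bad].round(4).tolist()})"
            )

    @property
    def b0_flags(self) -> np.ndarray:
        return self.bvals < self.b0_threshold

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def direction_indices(self) -> np.ndarray:
        """Indices of diffusion-weighted (non-b0) volumes."""
        return np.flatnonzero(~self.b0_flags)

    def __len__(self) -> int:
        return self.n_volumes


@dataclass(frozen=True)
class DirectionSample:
    """An ordered subset of volumes selected from a parent scheme."""

    indices: tuple
    method: str  # one of {"KS", "RandomKS", "Shuffle", "B0Swap"}
    parent: GradientScheme
    seed: Optional[int] = None

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise GradientValidationError("DirectionSample indices must be unique")
        object.__setattr__(self, "indices", idx)

    def to_json(self) -> str:
        return json.dumps(
            {"method": self.method, "seed": self.seed, "indices": list(self.indices)}
        )


def _read_rows(source: Union[str, Path, IO]) -> list:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise GradientFormatError(f"non-numeric token in gradient table: {exc}")
    return rows


def load_fsl_gradients(
    bval_source: Union[str, Path, IO],
    bvec_source: Union[str, Path, IO],
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> GradientScheme:
    """Read an FSL-style gradient table (bval: 1xN row; bvec: 3xN rows).

    Non-b0 vectors are renormalized to unit length; a norm outside
    [0.9, 1.1] raises :class:`GradientValidationError`.
    """
    bval_rows = _read_rows(bval_source)
    bvec_rows = _read_rows(bvec_source)
    if len(bval_rows) != 1:
        raise GradientFormatError(f"bval file must hold one row, got {len(bval_rows)}")
    if len(bvec_rows) != 3:
        raise GradientFormatError(f"bvec file must hold three rows, got {len(bvec_rows)}")
    bvals = np.array(bval_rows[0], dtype=float)
    lengths = {len(r) for r in bvec_rows} | {bvals.shape[0]}
    if len(lengths) != 1:
        raise GradientFormatError(f"bval/bvec row lengths disagree: {sorted(lengths)}")
    bvecs = np.array(bvec_rows, dtype=float).T  # (N, 3)

    b0 = bvals < b0_threshold
    norms = np.linalg.norm(bvecs, axis=1)
    out_of_band = (~b0) & ((norms < 0.9) | (norms > 1.1))
    if np.any(out_of_band):
        raise GradientValidationError(
            f"bvec norm outside [0.9, 1.1] at volume(s) {np.flatnonzero(out_of_band).tolist()}"
        )
    fix = (~b0) & (norms > 0)
    bvecs = bvecs.copy()
    bvecs[fix] /= norms[fix, None]
    return GradientScheme(bvals=bvals, bvecs=bvecs, b0_threshold=b0_threshold)


def save_fsl_gradients(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """Write FSL bval (1xN) and bvec (3xN) text files."""
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    lines = [" ".join(f"{v:.8f}" for v in scheme.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def hemisphere_distance(g1, g2) -> float:
    """Euclidean distance between two unit directions after antipodal
    identification: ``min(|g1 - g2|, |g1 + g2|)``."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    for g in (g1, g2):
        if abs(np.linalg.norm(g) - 1.0) > 1e-3:
            raise GradientValidationError(f"non-unit direction {g}")
    return float(min(np.linalg.norm(g1 - g2), np.linalg.norm(g1 + g2)))


def hemisphere_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise antipodally-folded distances for unit row vectors."""
    v = np.asarray(vectors, dtype=float)
    # |a-b|^2 = 2 - 2 a.b ; |a+b|^2 = 2 + 2 a.b  =>  min uses |a.b|
    dots = np.clip(np.abs(v @ v.T), 0.0, 1.0)
    d2 = 2.0 - 2.0 * dots
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def _greedy_ks(dist: np.ndarray, cand: np.ndarray, selected: list, k: int) -> list:
    """Extend `selected` (positions into `cand`) to length k by the
    maximin rule with lowest-index tie-breaking."""
    n = len(cand)
    sel = list(selected)
    if not sel:
        # first pair: maximize pairwise distance, lowest (i, j) on ties
        best = (-1.0, None)
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] > best[0] + 1e-12:
                    best = (dist[i, j], (i, j))
        sel = list(best[1])
    mind = np.min(dist[:, sel], axis=1)
    while len(sel) < k:
        masked = mind.copy()
        masked[sel] = -np.inf
        # np.argmax returns the first (lowest-index) maximizer on ties
        nxt = int(np.argmax(masked))
        sel.append(nxt)
        mind = np.minimum(mind, dist[:, nxt])
    return sel


def kennard_stone_sample(scheme: GradientScheme, k: int) -> DirectionSample:
    """Deterministic Kennard-Stone maximin subset of k directions.

    The first two picks are the most distant pair (after antipodal
    folding); every further pick maximizes its minimum distance to the
    already-selected set.  Ties break to the lowest volume index, making
    the output fully deterministic; samples are nested (the j-sample is a
    prefix of the k-sample for j <= k).
    """
    cand = scheme.direction_indices
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(cand):
        raise ValueError(f"k={k} exceeds {len(cand)} available directions")
    dist = hemisphere_distance_matrix(scheme.bvecs[cand])
    sel = _greedy_ks(dist, cand, [], k)
    return DirectionSample(indices=tuple(cand[sel]), method="KS", parent=scheme)


def random_ks_sample(scheme: GradientScheme, k: int, seed: int) -> DirectionSample:
    """Kennard-Stone with a seeded uniformly random first pick.

    The random stream is ``numpy.random.default_rng(seed)``; exactly one
    draw (``rng.integers(n_candidates)``) selects the first direction,
    after which the deterministic KS maximin rule applies.
    """
    cand = scheme.direction_indices
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(cand):
        raise ValueError(f"k={k} exceeds {len(cand)} available directions")
    rng = np.random.default_rng(seed)
    first = int(rng.integers(len(cand)))
    dist = hemisphere_distance_matrix(scheme.bvecs[cand])
    sel = _greedy_ks(dist, cand, [first], k) if k > 1 else [first]
    return DirectionSample(
        indices=tuple(cand[sel]), method="RandomKS", parent=scheme, seed=int(seed)
    )


def subset_scheme(
    scheme: GradientScheme,
    sample: Union[DirectionSample, Sequence[int]],
    include_b0: bool = True,
) -> GradientScheme:
    """Build the sub-scheme holding the sampled volumes (b0s first when
    ``include_b0``), e.g. to feed tensor fitting."""
    idx = list(sample.indices) if isinstance(sample, DirectionSample) else list(sample)
    order = (list(np.flatnonzero(scheme.b0_flags)) if include_b0 else []) + idx
    return GradientScheme(
        bvals=scheme.bvals[order],
        bvecs=scheme.bvecs[order],
        b0_threshold=scheme.b0_threshold,
    )
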