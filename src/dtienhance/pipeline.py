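"""Patch extraction, normalization, training and sliding-window inference.

Training follows the patch regime of the enhancement method: the
8-channel input (T1, b0, six diffusion-weighted volumes, each z-scored
image-wise over the brain mask) is cut into overlapping patches, patches
containing only background are discarded, and the network minimizes an
L1 loss restricted to white-matter voxels against per-coefficient
z-scored tensor targets (statistics from the training set's WM voxels).
Inference slides the unfiltered patch grid over the volume, averages
overlapping predictions voxelwise and de-normalizes with the stats
stored in the checkpoint.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import DOWN_FACTOR, NetworkConfig, UNet3D, build_model
from .tensor import DiffusionTensorField

__all__ = [
    "PatchGrid",
    "NormalizationStats",
    "TrainConfig",
    "TrainingSubject",
    "Checkpoint",
    "plan_patches",
    "discard_background_patches",
    "normalize_inputs",
    "wm_masked_l1",
    "compute_norm_stats",
    "train",
    "predict",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# patch planning


@dataclass(frozen=True)
class PatchGrid:
    patch_size: Tuple[int, int, int]
    overlap: Tuple[int, int, int]
    origins: Tuple[Tuple[int, int, int], ...]
    volume_shape: Tuple[int, int, int]
    padded_shape: Tuple[int, int, int]

    @property
    def stride(self) -> Tuple[int, int, int]:
        return tuple(p - o for p, o in zip(self.patch_size, self.overlap))

    @property
    def n_patches(self) -> int:
        return len(self.origins)


def _as_triple(x) -> Tuple[int, int, int]:
    if np.isscalar(x):
        return (int(x),) * 3
    t = tuple(int(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected scalar or 3 values, got {x!r}")
    return t


def plan_patches(volume_shape, patch_size, overlap) -> PatchGrid:
    """Overlapping patch origins covering the (padded) volume.

    Origins sit at multiples of ``stride = patch_size - overlap``; when
    the last regular origin does not reach the volume edge, an extra
    origin clamped flush with the edge is appended.  Volumes smaller
    than the patch are zero-padded up to the patch size.
    """
    shape = _as_triple(volume_shape)
    patch = _as_triple(patch_size)
    over = _as_triple(overlap)
    stride = tuple(p - o for p, o in zip(patch, over))
    if any(s <= 0 for s in stride):
        raise ValueError(f"overlap {over} must be smaller than patch {patch}")
    padded = tuple(max(s, p) for s, p in zip(shape, patch))
    axes = []
    for s, p, st in zip(padded, patch, stride):
        starts = list(range(0, s - p + 1, st))
        if starts[-1] + p < s:
            starts.append(s - p)  # clamp the last patch flush with the edge
        axes.append(starts)
    origins = tuple(
        (a, b, c) for a in axes[0] for b in axes[1] for c in axes[2]
    )
    return PatchGrid(
        patch_size=patch,
        overlap=over,
        origins=origins,
        volume_shape=shape,
        padded_shape=padded,
    )


def pad_to(volume: np.ndarray, padded_shape) -> np.ndarray:
    """Zero-pad the trailing spatial region up to padded_shape (leading
    channel axes untouched)."""
    spatial = volume.shape[-3:]
    pads = [(0, 0)] * (volume.ndim - 3) + [
        (0, ps - s) for s, ps in zip(spatial, padded_shape)
    ]
    if all(p == (0, 0) for p in pads):
        return volume
    return np.pad(volume, pads)


def extract_patch(volume: np.ndarray, origin, patch_size) -> np.ndarray:
    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_size))
    return volume[(Ellipsis,) + sl]


def discard_background_patches(grid: PatchGrid, brain_mask: np.ndarray) -> PatchGrid:
    """Keep only patches overlapping the mask (training grids only —
    inference always uses the full grid)."""
    mask = pad_to(np.asarray(brain_mask, dtype=bool), grid.padded_shape)
    keep = tuple(
        o for o in grid.origins if extract_patch(mask, o, grid.patch_size).any()
    )
    return PatchGrid(
        patch_size=grid.patch_size,
        overlap=grid.overlap,
        origins=keep,
        volume_shape=grid.volume_shape,
        padded_shape=grid.padded_shape,
    )


# ---------------------------------------------------------------------------
# normalization


def _zscore(channel: np.ndarray, mask: np.ndarray, label: str) -> np.ndarray:
    vals = channel[mask]
    mu, sd = float(vals.mean()), float(vals.std())
    if sd == 0.0:
        warnings.warn(f"channel {label!r} is constant over the mask; zeroed")
        return np.zeros_like(channel)
    return (channel - mu) / sd


def normalize_inputs(
    t1: np.ndarray,
    b0: np.ndarray,
    dwi_channels: np.ndarray,
    brain_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Stack the 8 model input channels, each z-scored image-wise.

    ``dwi_channels`` is (X, Y, Z, 6); returns (8, X, Y, Z) ordered
    [T1, b0, dwi_1..dwi_6].
    """
    t1 = np.asarray(t1, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    dwi = np.asarray(dwi_channels, dtype=float)
    if b0.shape != t1.shape or dwi.shape[:3] != t1.shape:
        raise ValueError("input channels are not on one grid")
    mask = (
        np.ones(t1.shape, dtype=bool)
        if brain_mask is None
        else np.asarray(brain_mask, dtype=bool)
    )
    if mask.shape != t1.shape:
        raise ValueError("mask is not on the channel grid")
    chans = [_zscore(t1, mask, "t1"), _zscore(b0, mask, "b0")]
    for i in range(dwi.shape[3]):
        chans.append(_zscore(dwi[..., i], mask, f"dwi{i}"))
    return np.stack(chans, axis=0)


@dataclass(frozen=True)
class NormalizationStats:
    """Per-coefficient mean/std of tensor targets over training WM voxels."""

    mean: np.ndarray  # (6,)
    std: np.ndarray  # (6,)

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float).reshape(6)
        std = np.asarray(self.std, dtype=float).reshape(6)
        if np.any(std <= 0):
            raise ValueError("normalization std must be > 0 for all 6 coefficients")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)

    def normalize(self, coeffs: np.ndarray) -> np.ndarray:
        return (coeffs - self.mean[:, None, None, None]) / self.std[:, None, None, None]

    def denormalize(self, coeffs: np.ndarray) -> np.ndarray:
        return coeffs * self.std[:, None, None, None] + self.mean[:, None, None, None]


def compute_norm_stats(
    targets: Sequence[np.ndarray], wm_masks: Sequence[np.ndarray]
) -> NormalizationStats:
    """Pool the training subjects' WM voxels per coefficient."""
    cols = []
    for coeffs, wm in zip(targets, wm_masks):
        cols.append(np.asarray(coeffs)[:, np.asarray(wm, dtype=bool)])
    pooled = np.concatenate(cols, axis=1)  # (6, total WM voxels)
    std = pooled.std(axis=1)
    std = np.where(std > 0, std, 1.0)
    return NormalizationStats(mean=pooled.mean(axis=1), std=std)


# ---------------------------------------------------------------------------
# loss


def wm_masked_l1(pred: np.ndarray, target: np.ndarray, wm_mask: np.ndarray) -> float:
    """Mean absolute difference over (WM voxels x channels); 0 when the
    patch holds no WM."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    wm = np.asarray(wm_mask, dtype=bool)
    if pred.shape != target.shape or pred.shape[-3:] != wm.shape:
        raise ValueError("shape mismatch between pred/target/mask")
    n = int(wm.sum())
    if n == 0:
        return 0.0
    diff = np.abs(pred - target)[..., wm]
    return float(diff.mean())


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Hyperparameters; defaults are the published training regime."""

    epochs: int = 100
    lr: float = 1e-4
    batch_size: int = 8
    patch_size: int = 64
    overlap: int = 32
    max_steps: Optional[int] = None
    seed: int = 0

    def to_dict(self) -> Dict:
        return {
            "epochs": self.epochs,
            "lr": self.lr,
            "batch_size": self.batch_size,
            "patch_size": self.patch_size,
            "overlap": self.overlap,
            "max_steps": self.max_steps,
            "seed": self.seed,
        }


@dataclass
class TrainingSubject:
    """In-memory channels and targets for one subject."""

    channels: np.ndarray  # (8, X, Y, Z), already z-scored
    target: np.ndarray  # (6, X, Y, Z), raw tensor coefficients (mm^2/s)
    wm_mask: np.ndarray
    brain_mask: np.ndarray
    name: str = "subject"


@dataclass
class Checkpoint:
    """Serialized model + everything inference needs."""

    weights: Dict[str, np.ndarray]
    net_config: NetworkConfig
    stats: NormalizationStats
    train_config: Optional[Dict] = None
    loss_history: Optional[List[float]] = None
    schema_version: int = 1

    def save(self, path) -> None:
        meta = {
            "schema_version": self.schema_version,
            "net_config": self.net_config.to_dict(),
            "train_config": self.train_config,
            "loss_history": self.loss_history,
        }
        arrays = {f"w::{k}": v for k, v in self.weights.items()}
        np.savez_compressed(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            stats_mean=self.stats.mean,
            stats_std=self.stats.std,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            weights = {
                k[len("w::"):]: z[k] for k in z.files if k.startswith("w::")
            }
            stats = NormalizationStats(mean=z["stats_mean"], std=z["stats_std"])
        return cls(
            weights=weights,
            net_config=NetworkConfig.from_dict(meta["net_config"]),
            stats=stats,
            train_config=meta.get("train_config"),
            loss_history=meta.get("loss_history"),
            schema_version=meta.get("schema_version", 1),
        )

    def build(self) -> UNet3D:
        model = build_model(self.net_config)
        model.load_state_dict(self.weights)
        return model


def _subject_patches(subject: TrainingSubject, cfg: TrainConfig):
    grid = plan_patches(
        subject.brain_mask.shape, cfg.patch_size, cfg.overlap
    )
    grid = discard_background_patches(grid, subject.brain_mask)
    return grid


def train(
    subjects: Sequence[TrainingSubject],
    net_config: NetworkConfig,
    train_config: Optional[TrainConfig] = None,
) -> Checkpoint:
    """WM-masked L1 patch training with Adam.

    Patches are pre-planned per subject, background-only patches are
    dropped, and the patch order is reshuffled every epoch with the run
    seed.  Raises if no trainable patches exist or the loss goes
    non-finite.
    """
    cfg = train_config or TrainConfig()
    stats = compute_norm_stats(
        [s.target for s in subjects], [s.wm_mask for s in subjects]
    )

    samples = []  # (subject index, origin)
    padded = {}
    for si, s in enumerate(subjects):
        grid = _subject_patches(s, cfg)
        if grid.n_patches == 0:
            continue
        padded[si] = (
            pad_to(s.channels, grid.padded_shape),
            pad_to(stats.normalize(s.target), grid.padded_shape),
            pad_to(s.wm_mask.astype(bool), grid.padded_shape),
        )
        samples += [(si, o) for o in grid.origins]
        psize = grid.patch_size
    if not samples:
        raise RuntimeError("no trainable patches (all patches are background)")

    model = build_model(net_config)
    opt = model.make_optimizer(lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)

    history: List[float] = []
    step = 0
    done = False
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        for lo in range(0, len(order), cfg.batch_size):
            batch = [samples[i] for i in order[lo:lo + cfg.batch_size]]
            xs, ys, wms = [], [], []
            for si, origin in batch:
                ch, tg, wm = padded[si]
                xs.append(extract_patch(ch, origin, psize))
                ys.append(extract_patch(tg, origin, psize))
                wms.append(extract_patch(wm, origin, psize))
            x = np.stack(xs)
            y = np.stack(ys)
            wm = np.stack(wms)  # (B, D, H, W)

            pred = model.forward(x)
            diff = pred - y
            B = len(batch)
            loss = 0.0
            grad = np.zeros_like(pred)
            for b in range(B):
                n = int(wm[b].sum())
                if n == 0:
                    continue
                m = wm[b][None]  # broadcast over channels
                loss += float(np.abs(diff[b])[:, wm[b]].mean())
                grad[b] = np.sign(diff[b]) * m / (n * pred.shape[1])
            loss /= B
            grad /= B
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at step {step}: {loss}")
            model.zero_grad()
            model.backward(grad)
            opt.step()
            history.append(loss)
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
        logger.info("epoch %d done, last loss %.5f", epoch, history[-1])
        if done:
            break

    return Checkpoint(
        weights=model.state_dict(),
        net_config=net_config,
        stats=stats,
        train_config=cfg.to_dict(),
        loss_history=history,
    )


# ---------------------------------------------------------------------------
# inference


def reconstruct_from_patches(
    patch_fn: Callable[[Tuple[int, int, int], np.ndarray], np.ndarray],
    channels: np.ndarray,
    patch_size,
    overlap,
    n_out: int,
) -> np.ndarray:
    """Sliding-window apply + unweighted overlap averaging.

    ``patch_fn(origin, patch)`` maps an input patch (C, p, p, p) to an
    output patch (n_out, p, p, p).  Returns the reconstructed volume on
    the *unpadded* input grid.
    """
    shape = channels.shape[-3:]
    grid = plan_patches(shape, patch_size, overlap)
    ch = pad_to(channels, grid.padded_shape)
    # accumulate in extended precision so that averaging identical
    # contributions is bitwise exact even for odd overlap counts
    # (e.g. (x + x + x) / 3 == x after rounding back to float64)
    acc = np.zeros((n_out,) + grid.padded_shape, dtype=np.longdouble)
    cnt = np.zeros(grid.padded_shape)
    for origin in grid.origins:
        patch = extract_patch(ch, origin, grid.patch_size)
        out = patch_fn(origin, patch)
        sl = tuple(slice(o, o + p) for o, p in zip(origin, grid.patch_size))
        acc[(slice(None),) + sl] += out
        cnt[sl] += 1.0
    acc /= cnt[None]
    crop = tuple(slice(0, s) for s in shape)
    return np.asarray(acc[(slice(None),) + crop], dtype=np.float64)


def predict(
    channels: np.ndarray,
    checkpoint: Checkpoint,
    brain_mask: Optional[np.ndarray] = None,
    affine: Optional[np.ndarray] = None,
    patch_size: Optional[int] = None,
    overlap: Optional[int] = None,
) -> DiffusionTensorField:
    """Full-volume enhanced-tensor inference.

    ``channels`` is the (8, X, Y, Z) z-scored input stack; the unfiltered
    patch grid is applied, overlaps averaged, and the output de-normalized
    with the checkpoint's training-set statistics.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.shape[0] != checkpoint.net_config.in_channels:
        raise ValueError(
            f"checkpoint expects {checkpoint.net_config.in_channels} channels, "
            f"got {channels.shape[0]}"
        )
    tc = checkpoint.train_config or {}
    psize = patch_size if patch_size is not None else tc.get("patch_size", 64)
    over = overlap if overlap is not None else tc.get("overlap", psize // 2)
    model = checkpoint.build()

    def run(origin, patch):
        return model.forward(patch[None])[0]

    norm = reconstruct_from_patches(
        run, channels, psize, over, checkpoint.net_config.out_channels
    )
    coeffs = checkpoint.stats.denormalize(norm)
    return DiffusionTensorField(
        coeffs=coeffs,
        affine=np.eye(4) if affine is None else affine,
        mask=brain_mask,
    )
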