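"""Similarity metrics over region masks and the hypothesis-testing harness.

Metrics: mean absolute error, structural similarity (Gaussian window,
sigma 1.5, data range from the reference volume over the mask) and
zero-normalized cross-correlation (Pearson correlation of masked
intensities).  Group comparisons pass through a normalcy gate
(Shapiro-Wilk at 0.05) that selects between the paired/independent
t-test and the Wilcoxon signed-rank / Mann-Whitney U test, with
Bonferroni-corrected significance (alpha / n_comparisons).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.metrics import structural_similarity

from .tensor import ScalarMaps

__all__ = [
    "RegionReport",
    "StatResult",
    "mae",
    "ssim",
    "ncc",
    "region_report",
    "compare_groups",
    "symmetric_difference_test",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
NORMALCY_ALPHA = 0.05


def _masked(a, b, mask):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    m = np.asarray(mask, dtype=bool)
    if m.shape != a.shape:
        raise ValueError("mask shape mismatch")
    if not m.any():
        raise ValueError("empty mask")
    return a, b, m


def mae(a, b, mask) -> float:
    """Mean absolute voxel difference over the mask."""
    a, b, m = _masked(a, b, mask)
    return float(np.abs(a - b)[m].mean())


def ssim(a, b, mask) -> float:
    """Masked structural similarity vs the reference volume ``b``.

    The SSIM map is computed with a Gaussian window (sigma 1.5) and the
    data range of the reference over the mask, then averaged over masked
    voxels.
    """
    a, b, m = _masked(a, b, mask)
    ref = b[m]
    drange = float(ref.max() - ref.min())
    if drange == 0.0:
        raise ValueError("reference volume is constant over the mask")
    _, smap = structural_similarity(
        b, a, data_range=drange, gaussian_weights=True, sigma=1.5, full=True
    )
    return float(smap[m].mean())


def ncc(a, b, mask) -> float:
    """Zero-normalized cross-correlation (Pearson r) of masked voxels."""
    a, b, m = _masked(a, b, mask)
    av, bv = a[m], b[m]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("constant input over the mask")
    return float(np.corrcoef(av, bv)[0, 1])


@dataclass
class RegionReport:
    """Per-region, per-scalar metric summary across subjects."""

    region: str
    scalar: str
    mae_mean: float
    mae_std: float
    ssim_mean: float
    ssim_std: float
    ncc_mean: float
    ncc_std: float
    n_subjects: int


def region_report(
    pred_maps: Sequence[ScalarMaps],
    ref_maps: Sequence[ScalarMaps],
    regions: Dict[str, np.ndarray],
    scalars: Sequence[str] = ("fa", "md", "ad", "rd"),
) -> List[RegionReport]:
    """MAE/SSIM/NCC per region per scalar, aggregated across subjects.

    ``pred_maps`` and ``ref_maps`` are parallel per-subject lists; empty
    regions are skipped with a warning.  Any labeled mask set works
    (e.g. the phantom's synthetic tract labels standing in for a tract
    atlas).
    """
    if len(pred_maps) != len(ref_maps):
        raise ValueError("pred/ref subject counts differ")
    reports = []
    for name, region_mask in regions.items():
        m = np.asarray(region_mask, dtype=bool)
        if not m.any():
            warnings.warn(f"region {name!r} is empty; skipped")
            continue
        for scalar in scalars:
            vals = {"mae": [], "ssim": [], "ncc": []}
            for p, r in zip(pred_maps, ref_maps):
                pv = p.as_dict()[scalar]
                rv = r.as_dict()[scalar]
                vals["mae"].append(mae(pv, rv, m))
                vals["ssim"].append(ssim(pv, rv, m))
                vals["ncc"].append(ncc(pv, rv, m))
            reports.append(
                RegionReport(
                    region=name,
                    scalar=scalar,
                    mae_mean=float(np.mean(vals["mae"])),
                    mae_std=float(np.std(vals["mae"])),
                    ssim_mean=float(np.mean(vals["ssim"])),
                    ssim_std=float(np.std(vals["ssim"])),
                    ncc_mean=float(np.mean(vals["ncc"])),
                    ncc_std=float(np.std(vals["ncc"])),
                    n_subjects=len(pred_maps),
                )
            )
    return reports


def reports_to_frame(reports: List[RegionReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for metric in ("mae", "ssim", "ncc"):
            rows.append(
                {
                    "region": r.region,
                    "scalar": r.scalar,
                    "metric": metric,
                    "mean": getattr(r, f"{metric}_mean"),
                    "std": getattr(r, f"{metric}_std"),
                    "n": r.n_subjects,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    alpha: float  # after correction
    significant: bool
    normal: Optional[bool] = None  # normalcy-gate outcome


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False  # degenerate; route to the exact-tie nonparametric branch
    return sps.shapiro(x).pvalue > NORMALCY_ALPHA


def _wilcoxon_or_trivial(diff: np.ndarray):
    if np.all(diff == 0):
        return 0.0, 1.0  # no evidence against symmetry around zero
    res = sps.wilcoxon(diff, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool,
    n_comparisons: int = 1,
    alpha: float = DEFAULT_ALPHA,
    force_normal: Optional[bool] = None,
) -> StatResult:
    """Normalcy-gated two-group comparison with Bonferroni correction.

    paired & normal -> paired t-test; paired & non-normal -> Wilcoxon
    signed-rank; unpaired & normal -> independent t-test; unpaired &
    non-normal -> Mann-Whitney U.  Two-sided throughout.
    ``force_normal`` overrides the Shapiro-Wilk gate (True selects the
    parametric branch, False the nonparametric one).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 values per group")
    corrected = alpha / n_comparisons
    if paired:
        if len(x) != len(y):
            raise ValueError("paired groups must have equal length")
        diff = x - y
        normal = _is_normal(diff) if force_normal is None else bool(force_normal)
        if normal:
            res = sps.ttest_rel(x, y)
            name, stat, p = "paired t", float(res.statistic), float(res.pvalue)
        else:
            stat, p = _wilcoxon_or_trivial(diff)
            name = "Wilcoxon signed-rank"
    else:
        normal = (
            (_is_normal(x) and _is_normal(y))
            if force_normal is None
            else bool(force_normal)
        )
        if normal:
            res = sps.ttest_ind(x, y)
            name, stat, p = "independent t", float(res.statistic), float(res.pvalue)
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            name, stat, p = "Mann-Whitney U", float(res.statistic), float(res.pvalue)
    return StatResult(
        test=name,
        statistic=stat,
        p_value=p,
        alpha=corrected,
        significant=bool(p < corrected),
        normal=normal,
    )


def symmetric_difference_test(
    baselines: Sequence[float],
    variants: Sequence[Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
) -> List[StatResult]:
    """Per-subject one-sample signed-rank test of (variant - baseline).

    For each subject the baseline value (e.g. the deterministic-subset
    error) is subtracted from that subject's variant values and a
    Wilcoxon signed-rank test checks symmetry around zero; alpha is
    Bonferroni-corrected by the number of subjects.
    """
    n_sub = len(baselines)
    if n_sub != len(variants):
        raise ValueError("one variant list per subject required")
    corrected = alpha / n_sub
    out = []
    for base, var in zip(baselines, variants):
        var = np.asarray(var, dtype=float)
        if len(var) < 5:
            raise ValueError("need >= 5 variant values per subject")
        diff = var - float(base)
        stat, p = _wilcoxon_or_trivial(diff)
        out.append(
            StatResult(
                test="one-sample signed-rank",
                statistic=stat,
                p_value=p,
                alpha=corrected,
                significant=bool(p < corrected),
                normal=None,
            )
        )
    return out
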