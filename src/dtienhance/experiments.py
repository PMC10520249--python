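"""Experiment generators and runners: the FA-vs-direction-count curve
and the three generalisation hypotheses.

The generalisation suite probes a trained enhancement model with four
kinds of 6-direction inputs built from one dense acquisition:

* ``LAR_KS``       - the single deterministic Kennard-Stone subset;
* ``LAR_Random``   - 10 randomized-KS subsets (random first pick);
* ``LAR_Shuffled`` - 5 seeded channel permutations of each random
  subset (50 inputs), testing order sensitivity;
* ``LAR_B0``       - each random subset with the b0 volume placed into
  one seeded direction slot (the displaced direction is dropped,
  channel 1 keeps b0), testing b0-position sensitivity.

Per-subject white-matter FA MAE against the dense-fit reference feeds a
one-sample signed-rank test (H1: random vs deterministic sampling) and
Mann-Whitney U tests (H2: order, H3: b0 position), all Bonferroni
corrected across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evaluation import DEFAULT_ALPHA, StatResult, compare_groups, mae, \
    symmetric_difference_test
from .gradients import (
    DirectionSample,
    GradientScheme,
    kennard_stone_sample,
    random_ks_sample,
    subset_scheme,
)
from .phantom import Phantom, simulate_acquisition
from .pipeline import Checkpoint, normalize_inputs, predict
from .tensor import fit_tensor, scalar_maps

__all__ = [
    "InputSpec",
    "ExperimentSet",
    "GeneralisationSubject",
    "GeneralisationResult",
    "fa_vs_directions",
    "build_experiment_sets",
    "run_generalisation",
    "checkpoint_fa_predictor",
]

SET_NAMES = ("LAR_KS", "LAR_Random", "LAR_Shuffled", "LAR_B0")
N_RANDOM = 10
N_SHUFFLES = 5


@dataclass(frozen=True)
class InputSpec:
    """One 8-channel model input: T1, b0, and six source volume indices.

    ``direction_slots`` are the volume indices feeding channels 2-7; for
    a b0-swap input one slot holds ``b0_index`` itself.
    """

    direction_slots: Tuple[int, int, int, int, int, int]
    b0_index: int
    method: str
    seeds: Tuple = ()
    parent_indices: Tuple = ()

    def provenance(self) -> Dict:
        return {
            "method": self.method,
            "seeds": list(self.seeds),
            "slots": list(self.direction_slots),
            "parent_indices": list(self.parent_indices),
            "b0_index": self.b0_index,
        }


@dataclass
class ExperimentSet:
    name: str
    inputs: List[InputSpec]

    def __post_init__(self):
        expected = {
            "LAR_KS": 1,
            "LAR_Random": N_RANDOM,
            "LAR_Shuffled": N_RANDOM * N_SHUFFLES,
            "LAR_B0": N_RANDOM,
        }
        if self.name in expected and len(self.inputs) != expected[self.name]:
            raise ValueError(
                f"{self.name} must hold {expected[self.name]} inputs, "
                f"got {len(self.inputs)}"
            )


def fa_vs_directions(
    phantoms: Sequence[Phantom],
    ks_counts: Sequence[int],
    snr: float,
    seed: int,
) -> pd.DataFrame:
    """Mean WM FA (with 95% CI) and error vs the dense fit per count.

    For each direction count k the deterministic KS k-subset of the
    dense scheme is fitted and the per-subject mean white-matter FA and
    mean |FA_k - FA_dense| are aggregated across subjects.
    """
    ks_counts = sorted(int(k) for k in ks_counts)
    if ks_counts and ks_counts[0] < 6:
        raise ValueError("6 diffusion gradient directions are the minimum")
    rows = []
    per_subject: Dict[int, Dict[str, List[float]]] = {
        k: {"mean_fa": [], "err": []} for k in ks_counts
    }
    for si, ph in enumerate(phantoms):
        dwi = simulate_acquisition(ph, snr=snr, seed=seed + si)
        scheme = ph.scheme
        dense_fit = fit_tensor(dwi, scheme, mask=ph.brain_mask)
        fa_dense = scalar_maps(dense_fit).fa
        wm = ph.wm_mask
        for k in ks_counts:
            if k == len(scheme.direction_indices):
                sub_idx = list(scheme.direction_indices)
            else:
                sub_idx = list(kennard_stone_sample(scheme, k).indices)
            vol_idx = list(np.flatnonzero(scheme.b0_flags)) + sub_idx
            sub_scheme = GradientScheme(
                bvals=scheme.bvals[vol_idx], bvecs=scheme.bvecs[vol_idx]
            )
            fit_k = fit_tensor(dwi[..., vol_idx], sub_scheme, mask=ph.brain_mask)
            fa_k = scalar_maps(fit_k).fa
            per_subject[k]["mean_fa"].append(float(fa_k[wm].mean()))
            per_subject[k]["err"].append(float(np.abs(fa_k - fa_dense)[wm].mean()))
    for k in ks_counts:
        vals = np.array(per_subject[k]["mean_fa"])
        errs = np.array(per_subject[k]["err"])
        n = len(vals)
        if n > 1:
            half = sps.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        rows.append(
            {
                "n_directions": k,
                "mean_wm_fa": float(vals.mean()),
                "ci95_half_width": float(half),
                "mean_abs_fa_error_vs_dense": float(errs.mean()),
                "n_subjects": n,
            }
        )
    return pd.DataFrame(rows)


def build_experiment_sets(
    dense_scheme: GradientScheme,
    random_seeds: Sequence[int],
    shuffle_seeds: Sequence[int],
    b0_slot_seeds: Sequence[int],
) -> Dict[str, ExperimentSet]:
    """All four input families for one subject's dense scheme."""
    if len(random_seeds) != N_RANDOM:
        raise ValueError(f"need {N_RANDOM} random seeds, got {len(random_seeds)}")
    if len(shuffle_seeds) != N_SHUFFLES:
        raise ValueError(f"need {N_SHUFFLES} shuffle seeds, got {len(shuffle_seeds)}")
    if len(b0_slot_seeds) != N_RANDOM:
        raise ValueError(f"need {N_RANDOM} b0 seeds, got {len(b0_slot_seeds)}")
    b0_index = int(np.flatnonzero(dense_scheme.b0_flags)[0])

    ks = kennard_stone_sample(dense_scheme, 6)
    lar_ks = ExperimentSet(
        "LAR_KS",
        [InputSpec(tuple(ks.indices), b0_index, "KS")],
    )

    randoms: List[InputSpec] = []
    for s in random_seeds:
        smp = random_ks_sample(dense_scheme, 6, seed=int(s))
        randoms.append(
            InputSpec(tuple(smp.indices), b0_index, "RandomKS", seeds=(int(s),))
        )
    lar_random = ExperimentSet("LAR_Random", randoms)

    shuffled: List[InputSpec] = []
    for ri, rspec in enumerate(randoms):
        for ss in shuffle_seeds:
            rng = np.random.default_rng([int(ss), ri])
            perm = rng.permutation(6)
            shuffled.append(
                InputSpec(
                    tuple(np.array(rspec.direction_slots)[perm]),
                    b0_index,
                    "Shuffle",
                    seeds=(int(rspec.seeds[0]), int(ss)),
                    parent_indices=rspec.direction_slots,
                )
            )
    lar_shuffled = ExperimentSet("LAR_Shuffled", shuffled)

    b0_swapped: List[InputSpec] = []
    for rspec, bs in zip(randoms, b0_slot_seeds):
        rng = np.random.default_rng(int(bs))
        slot = int(rng.integers(6))  # which of the 6 direction channels
        slots = list(rspec.direction_slots)
        slots[slot] = b0_index  # displaced direction is dropped
        b0_swapped.append(
            InputSpec(
                tuple(slots),
                b0_index,
                "B0Swap",
                seeds=(int(rspec.seeds[0]), int(bs)),
                parent_indices=rspec.direction_slots,
            )
        )
    lar_b0 = ExperimentSet("LAR_B0", b0_swapped)

    return {
        "LAR_KS": lar_ks,
        "LAR_Random": lar_random,
        "LAR_Shuffled": lar_shuffled,
        "LAR_B0": lar_b0,
    }


@dataclass
class GeneralisationSubject:
    """Everything needed to assemble model inputs for one subject."""

    name: str
    t1: np.ndarray
    dwi: np.ndarray  # (X, Y, Z, N) dense noisy acquisition
    scheme: GradientScheme
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    reference_fa: np.ndarray  # FA of the dense fit


def assemble_channels(subject: GeneralisationSubject, spec: InputSpec) -> np.ndarray:
    """Z-scored (8, X, Y, Z) stack for one input specification."""
    b0_vol = subject.dwi[..., spec.b0_index]
    dwi6 = subject.dwi[..., list(spec.direction_slots)]
    return normalize_inputs(subject.t1, b0_vol, dwi6, subject.brain_mask)


def checkpoint_fa_predictor(checkpoint: Checkpoint) -> Callable:
    """Wrap a checkpoint as a (channels, subject) -> FA volume callable."""

    def _predict(channels: np.ndarray, subject: GeneralisationSubject) -> np.ndarray:
        field = predict(channels, checkpoint, brain_mask=subject.brain_mask)
        return scalar_maps(field).fa

    return _predict


@dataclass
class GeneralisationResult:
    table: pd.DataFrame  # columns: subject, set, input index, fa_mae
    h1: List[StatResult]
    h2: List[StatResult]
    h3: List[StatResult]

    def summary(self) -> Dict[str, Dict]:
        out = {}
        for name, results in (("H1", self.h1), ("H2", self.h2), ("H3", self.h3)):
            out[name] = {
                "n_subjects": len(results),
                "n_significant": sum(r.significant for r in results),
                "corrected_alpha": results[0].alpha if results else None,
            }
        return out


def run_generalisation(
    predictor: Callable[[np.ndarray, GeneralisationSubject], np.ndarray],
    subjects: Sequence[GeneralisationSubject],
    sets_per_subject: Sequence[Dict[str, ExperimentSet]],
    alpha: float = DEFAULT_ALPHA,
    n_comparisons: Optional[int] = None,
) -> GeneralisationResult:
    """Predict every input set, score WM FA MAE vs the dense reference
    and run the three hypothesis tests.

    ``predictor(channels, subject)`` returns an FA volume; passing a
    stub instead of a trained checkpoint lets the harness itself be
    validated.  ``n_comparisons`` defaults to the number of subjects
    (the Bonferroni factor is a parameter, not a constant).
    """
    if len(subjects) != len(sets_per_subject):
        raise ValueError("one set dict per subject required")
    n_comp = n_comparisons if n_comparisons is not None else len(subjects)
    rows = []
    errors: Dict[str, List[List[float]]] = {name: [] for name in SET_NAMES}
    for subject, sets in zip(subjects, sets_per_subject):
        wm = subject.wm_mask
        for name in SET_NAMES:
            per_set = []
            for ii, spec in enumerate(sets[name].inputs):
                channels = assemble_channels(subject, spec)
                fa = predictor(channels, subject)
                err = mae(fa, subject.reference_fa, wm)
                per_set.append(err)
                rows.append(
                    {
                        "subject": subject.name,
                        "set": name,
                        "input": ii,
                        "fa_mae": err,
                    }
                )
            errors[name].append(per_set)

    h1 = symmetric_difference_test(
        baselines=[e[0] for e in errors["LAR_KS"]],
        variants=errors["LAR_Random"],
        alpha=alpha,
    )
    # Bonferroni factor across subjects applies to the per-subject tests
    h1 = [
        StatResult(r.test, r.statistic, r.p_value, alpha / n_comp,
                   r.p_value < alpha / n_comp, r.normal)
        for r in h1
    ]
    h2, h3 = [], []
    for si in range(len(subjects)):
        h2.append(
            compare_groups(
                errors["LAR_Random"][si],
                errors["LAR_Shuffled"][si],
                paired=False,
                n_comparisons=n_comp,
                alpha=alpha,
                force_normal=False,  # the harness prescribes Mann-Whitney here
            )
        )
        h3.append(
            compare_groups(
                errors["LAR_Random"][si],
                errors["LAR_B0"][si],
                paired=False,
                n_comparisons=n_comp,
                alpha=alpha,
                force_normal=False,
            )
        )
    return GeneralisationResult(table=pd.DataFrame(rows), h1=h1, h2=h2, h3=h3)
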