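import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtienhance.gradients import (
    GradientFormatError,
    GradientScheme,
    GradientValidationError,
    hemisphere_distance,
    hemisphere_distance_matrix,
    kennard_stone_sample,
    load_fsl_gradients,
    random_ks_sample,
    save_fsl_gradients,
    subset_scheme,
)


def _scheme(vecs, bval=1000.0, n_b0=1):
    vecs = np.asarray(vecs, dtype=float)
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(len(vecs), bval)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), vecs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


# ---------------------------------------------------------------------------
# loading / validation


def test_load_fsl_roundtrip(tmp_path, dense_scheme):
    save_fsl_gradients(dense_scheme, tmp_path / "a.bval", tmp_path / "a.bvec")
    back = load_fsl_gradients(tmp_path / "a.bval", tmp_path / "a.bvec")
    assert np.allclose(back.bvals, dense_scheme.bvals)
    assert np.allclose(back.bvecs, dense_scheme.bvecs, atol=1e-7)


def test_load_fsl_basic():
    bval = io.StringIO("0 1000 1000\n")
    bvec = io.StringIO("0 1 0\n0 0 1\n0 0 0\n")
    s = load_fsl_gradients(bval, bvec)
    assert list(s.b0_flags) == [True, False, False]
    assert list(s.direction_indices) == [1, 2]


def test_load_fsl_renormalizes_near_unit():
    bval = io.StringIO("0 1000\n")
    bvec = io.StringIO("0 1.05\n0 0\n0 0\n")
    s = load_fsl_gradients(bval, bvec)
    assert np.isclose(np.linalg.norm(s.bvecs[1]), 1.0)


def test_load_fsl_rejects_out_of_band_norm():
    bval = io.StringIO("0 1000\n")
    bvec = io.StringIO("0 0.866\n0 0\n0 0\n")
    with pytest.raises(GradientValidationError):
        load_fsl_gradients(bval, bvec)


def test_load_fsl_rejects_length_mismatch():
    with pytest.raises(GradientFormatError):
        load_fsl_gradients(
            io.StringIO("0 1000 1000\n"), io.StringIO("0 1\n0 0\n0 0\n")
        )


def test_load_fsl_rejects_non_numeric():
    with pytest.raises(GradientFormatError):
        load_fsl_gradients(io.StringIO("0 abc\n"), io.StringIO("0 1\n0 0\n0 0\n"))


def test_scheme_rejects_non_unit_direction():
    with pytest.raises(GradientValidationError):
        GradientScheme(bvals=np.array([1000.0]), bvecs=np.array([[0.5, 0.0, 0.0]]))


def test_b0_bvec_may_be_zero():
    s = GradientScheme(
        bvals=np.array([0.0, 1000.0]), bvecs=np.array([[0, 0, 0], [1, 0, 0]], float)
    )
    assert s.b0_flags[0] and not s.b0_flags[1]


# ---------------------------------------------------------------------------
# hemisphere distance


def test_hemisphere_distance_examples():
    e = np.eye(3)
    assert hemisphere_distance(e[0], e[0]) == 0.0
    assert hemisphere_distance(e[0], -e[0]) == pytest.approx(0.0, abs=1e-12)
    assert hemisphere_distance(e[0], e[1]) == pytest.approx(np.sqrt(2.0))


def test_hemisphere_distance_rejects_non_unit():
    with pytest.raises(GradientValidationError):
        hemisphere_distance([2.0, 0.0, 0.0], [1.0, 0.0, 0.0])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_hemisphere_distance_matrix_matches_pairwise(seed):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((6, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    D = hemisphere_distance_matrix(v)
    assert np.allclose(D, D.T)
    for i in range(6):
        for j in range(6):
            assert D[i, j] == pytest.approx(
                hemisphere_distance(v[i], v[j]), abs=1e-9
            )


def test_hemisphere_distance_antipodal_invariance(rng):
    v = rng.standard_normal((10, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    flipped = v.copy()
    flipped[::2] *= -1.0
    assert np.allclose(
        hemisphere_distance_matrix(v), hemisphere_distance_matrix(flipped)
    )


# ---------------------------------------------------------------------------
# Kennard-Stone


def test_ks_small_example_picks_most_distant_pair():
    # three axes plus the diagonal: any axis pair attains the maximum
    # folded distance sqrt(2); lowest-index tie-break selects volumes (1, 2)
    s = _scheme([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]])
    smp = kennard_stone_sample(s, 2)
    assert smp.indices == (1, 2)


def test_ks_deterministic(dense_scheme):
    a = kennard_stone_sample(dense_scheme, 6)
    b = kennard_stone_sample(dense_scheme, 6)
    assert a.indices == b.indices
    assert a.method == "KS"


def test_ks_nesting(dense_scheme):
    full = kennard_stone_sample(dense_scheme, 12).indices
    for j in range(2, 12):
        assert kennard_stone_sample(dense_scheme, j).indices == full[:j]


def test_ks_antipodal_invariance(dense_scheme, rng):
    flip = rng.random(dense_scheme.n_volumes) < 0.5
    bvecs = dense_scheme.bvecs.copy()
    bvecs[flip] *= -1.0
    flipped = GradientScheme(bvals=dense_scheme.bvals, bvecs=bvecs)
    assert (
        kennard_stone_sample(flipped, 6).indices
        == kennard_stone_sample(dense_scheme, 6).indices
    )


def _greedy_oracle(vecs, first=None, k=4):
    """Independent re-implementation of the greedy maximin rule."""
    n = len(vecs)
    d = lambda i, j: hemisphere_distance(vecs[i], vecs[j])
    if first is None:
        best, pair = -1.0, None
        for i in range(n):
            for j in range(i + 1, n):
                if d(i, j) > best + 1e-12:
                    best, pair = d(i, j), (i, j)
        sel = list(pair)
    else:
        sel = [first]
    while len(sel) < k:
        best, pick = -1.0, None
        for i in range(n):
            if i in sel:
                continue
            mind = min(d(i, j) for j in sel)
            if mind > best + 1e-12:
                best, pick = mind, i
        sel.append(pick)
    return sel


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_ks_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((8, 3))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    s = _scheme(vecs)
    got = kennard_stone_sample(s, 4).indices
    want = tuple(np.array(_greedy_oracle(s.bvecs[1:], k=4)) + 1)
    assert got == want


def test_ks_k_bounds(dense_scheme):
    with pytest.raises(ValueError):
        kennard_stone_sample(dense_scheme, 1)
    with pytest.raises(ValueError):
        kennard_stone_sample(dense_scheme, 91)


# ---------------------------------------------------------------------------
# randomized KS


def test_random_ks_seeded_first_pick(dense_scheme):
    smp = random_ks_sample(dense_scheme, 6, seed=42)
    cand = dense_scheme.direction_indices
    expected_first = cand[np.random.default_rng(42).integers(len(cand))]
    assert smp.indices[0] == expected_first
    assert smp.method == "RandomKS" and smp.seed == 42
    # reproducible
    assert random_ks_sample(dense_scheme, 6, seed=42).indices == smp.indices


def test_random_ks_follows_greedy_after_first_pick(dense_scheme):
    smp = random_ks_sample(dense_scheme, 5, seed=7)
    cand = list(dense_scheme.direction_indices)
    first = cand.index(smp.indices[0])
    want = _greedy_oracle(dense_scheme.bvecs[cand], first=first, k=5)
    assert smp.indices == tuple(np.array(cand)[want])


def test_random_ks_full_size_is_permutation(dense_scheme):
    smp = random_ks_sample(dense_scheme, 90, seed=3)
    assert sorted(smp.indices) == list(dense_scheme.direction_indices)


def test_random_ks_spread_near_deterministic(dense_scheme):
    """Randomized starts stay within 25% of the deterministic KS spread."""
    def min_pairwise(sample):
        D = hemisphere_distance_matrix(dense_scheme.bvecs[list(sample.indices)])
        return D[np.triu_indices_from(D, 1)].min()

    ks_spread = min_pairwise(kennard_stone_sample(dense_scheme, 6))
    for seed in range(10):
        spread = min_pairwise(random_ks_sample(dense_scheme, 6, seed=seed))
        assert spread >= 0.75 * ks_spread


def test_ks_spread_beats_uniform_subsets(dense_scheme, rng):
    """KS minimum pairwise distance exceeds the 95th percentile of
    uniformly random 6-subsets."""
    cand = dense_scheme.direction_indices
    D = hemisphere_distance_matrix(dense_scheme.bvecs[cand])
    iu = np.triu_indices(6, 1)

    def spread(pos):
        return D[np.ix_(pos, pos)][iu].min()

    ks_pos = [list(cand).index(i) for i in kennard_stone_sample(dense_scheme, 6).indices]
    random_spreads = [
        spread(rng.choice(len(cand), 6, replace=False)) for _ in range(2000)
    ]
    assert spread(ks_pos) > np.percentile(random_spreads, 95)


# ---------------------------------------------------------------------------
# subset schemes


def test_subset_scheme_orders_b0_first(dense_scheme):
    smp = kennard_stone_sample(dense_scheme, 6)
    sub = subset_scheme(dense_scheme, smp)
    assert len(sub) == 7
    assert sub.b0_flags[0] and not sub.b0_flags[1:].any()
    assert np.allclose(sub.bvecs[1:], dense_scheme.bvecs[list(smp.indices)])


def test_direction_sample_rejects_duplicates(dense_scheme):
    from dtienhance.gradients import DirectionSample

    with pytest.raises(GradientValidationError):
        DirectionSample(indices=(1, 1, 2), method="KS", parent=dense_scheme)
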