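import numpy as np
import pytest

from dtienhance.experiments import (
    ExperimentSet,
    GeneralisationSubject,
    InputSpec,
    assemble_channels,
    build_experiment_sets,
    fa_vs_directions,
    run_generalisation,
)
from dtienhance.gradients import kennard_stone_sample, random_ks_sample
from dtienhance.phantom import PhantomSpec, build_phantom, simulate_acquisition
from dtienhance.tensor import fit_tensor, scalar_maps

RANDOM_SEEDS = list(range(10))
SHUFFLE_SEEDS = list(range(100, 105))
B0_SEEDS = list(range(200, 210))


# ---------------------------------------------------------------------------
# FA vs direction count


def test_fa_curve_noiseless_is_flat(phantom24):
    """Without noise every direction count recovers the same tensors, so
    the error against the dense fit vanishes for all k."""
    df = fa_vs_directions([phantom24], ks_counts=[6, 12, 90], snr=np.inf, seed=0)
    assert list(df["n_directions"]) == [6, 12, 90]
    assert np.allclose(df["mean_abs_fa_error_vs_dense"], 0.0, atol=1e-8)
    fa_ref = df["mean_wm_fa"].iloc[0]
    assert np.allclose(df["mean_wm_fa"], fa_ref, atol=1e-8)


def test_fa_curve_rejects_fewer_than_six():
    with pytest.raises(ValueError):
        fa_vs_directions([], ks_counts=[5, 6], snr=20.0, seed=0)


def test_fa_curve_columns_and_ci(phantom24):
    ph2 = build_phantom(PhantomSpec(grid_shape=(24, 24, 24), seed=3))
    df = fa_vs_directions([phantom24, ph2], ks_counts=[6, 90], snr=20.0, seed=0)
    assert set(df.columns) >= {"n_directions", "mean_wm_fa", "ci95_half_width",
                               "mean_abs_fa_error_vs_dense", "n_subjects"}
    assert (df["n_subjects"] == 2).all()
    assert (df["ci95_half_width"] >= 0).all()
    # k = 90 is the dense fit itself
    assert df.set_index("n_directions").loc[90, "mean_abs_fa_error_vs_dense"] \
        == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# experiment set construction


def test_build_experiment_sets_counts(dense_scheme):
    sets = build_experiment_sets(dense_scheme, RANDOM_SEEDS, SHUFFLE_SEEDS, B0_SEEDS)
    assert len(sets["LAR_KS"].inputs) == 1
    assert len(sets["LAR_Random"].inputs) == 10
    assert len(sets["LAR_Shuffled"].inputs) == 50
    assert len(sets["LAR_B0"].inputs) == 10


def test_build_experiment_sets_seed_validation(dense_scheme):
    with pytest.raises(ValueError):
        build_experiment_sets(dense_scheme, RANDOM_SEEDS[:5], SHUFFLE_SEEDS, B0_SEEDS)
    with pytest.raises(ValueError):
        build_experiment_sets(dense_scheme, RANDOM_SEEDS, SHUFFLE_SEEDS[:2], B0_SEEDS)
    with pytest.raises(ValueError):
        build_experiment_sets(dense_scheme, RANDOM_SEEDS, SHUFFLE_SEEDS, B0_SEEDS[:3])


def test_experiment_set_count_invariants(dense_scheme):
    spec = InputSpec((1, 2, 3, 4, 5, 6), 0, "KS")
    with pytest.raises(ValueError):
        ExperimentSet("LAR_Random", [spec])  # needs 10


def test_sets_match_sampling_rules(dense_scheme):
    sets = build_experiment_sets(dense_scheme, RANDOM_SEEDS, SHUFFLE_SEEDS, B0_SEEDS)
    ks = kennard_stone_sample(dense_scheme, 6)
    assert sets["LAR_KS"].inputs[0].direction_slots == ks.indices
    for seed, spec in zip(RANDOM_SEEDS, sets["LAR_Random"].inputs):
        assert spec.direction_slots == \
            random_ks_sample(dense_scheme, 6, seed=seed).indices
        assert spec.seeds == (seed,)


def test_shuffled_inputs_are_permutations(dense_scheme):
    sets = build_experiment_sets(dense_scheme, RANDOM_SEEDS, SHUFFLE_SEEDS, B0_SEEDS)
    randoms = {s.seeds[0]: s for s in sets["LAR_Random"].inputs}
    n_changed = 0
    for spec in sets["LAR_Shuffled"].inputs:
        parent = randoms[spec.seeds[0]]
        assert sorted(spec.direction_slots) == sorted(parent.direction_slots)
        assert spec.parent_indices == parent.direction_slots
        if spec.direction_slots != parent.direction_slots:
            n_changed += 1
    assert n_changed > 40  # almost all permutations actually reorder


def test_b0_swap_inputs_replace_one_direction(dense_scheme):
    sets = build_experiment_sets(dense_scheme, RANDOM_SEEDS, SHUFFLE_SEEDS, B0_SEEDS)
    b0_index = int(np.flatnonzero(dense_scheme.b0_flags)[0])
    randoms = {s.seeds[0]: s for s in sets["LAR_Random"].inputs}
    for spec in sets["LAR_B0"].inputs:
        assert spec.direction_slots.count(b0_index) == 1
        parent = randoms[spec.seeds[0]]
        kept = [i for i in spec.direction_slots if i != b0_index]
        assert set(kept) < set(parent.direction_slots)
        assert len(kept) == 5


def test_input_spec_provenance(dense_scheme):
    sets = build_experiment_sets(dense_scheme, RANDOM_SEEDS, SHUFFLE_SEEDS, B0_SEEDS)
    prov = sets["LAR_Shuffled"].inputs[0].provenance()
    assert prov["method"] == "Shuffle"
    assert len(prov["seeds"]) == 2
    assert len(prov["slots"]) == 6


# ---------------------------------------------------------------------------
# generalisation harness with stub predictors


def _make_subject(phantom, seed=0, snr=20.0):
    dwi = simulate_acquisition(phantom, snr=snr, seed=seed)
    fit = fit_tensor(dwi, phantom.scheme, mask=phantom.brain_mask)
    return GeneralisationSubject(
        name=f"sub{seed}",
        t1=phantom.t1,
        dwi=dwi,
        scheme=phantom.scheme,
        brain_mask=phantom.brain_mask,
        wm_mask=phantom.wm_mask,
        reference_fa=scalar_maps(fit).fa,
    )


@pytest.fixture(scope="module")
def gen_fixture():
    phantoms = [
        build_phantom(PhantomSpec(grid_shape=(24, 24, 24), seed=s))
        for s in (10, 11, 12)
    ]
    subjects = [_make_subject(ph, seed=i) for i, ph in enumerate(phantoms)]
    sets = [
        build_experiment_sets(ph.scheme, RANDOM_SEEDS, SHUFFLE_SEEDS, B0_SEEDS)
        for ph in phantoms
    ]
    return subjects, sets


def test_assemble_channels_contract(gen_fixture):
    subjects, sets = gen_fixture
    spec = sets[0]["LAR_KS"].inputs[0]
    ch = assemble_channels(subjects[0], spec)
    assert ch.shape == (8,) + subjects[0].t1.shape
    m = subjects[0].brain_mask
    for c in range(8):
        assert ch[c][m].mean() == pytest.approx(0.0, abs=1e-9)


def test_b0_swap_channel_duplicates_b0(gen_fixture):
    """In a b0-swap input one direction channel carries the (z-scored)
    b0 volume, i.e. it duplicates channel 1 exactly."""
    subjects, sets = gen_fixture
    spec = sets[0]["LAR_B0"].inputs[0]
    ch = assemble_channels(subjects[0], spec)
    slot = spec.direction_slots.index(spec.b0_index)
    assert np.allclose(ch[2 + slot], ch[1], atol=1e-12)


def test_harness_order_invariant_stub_accepts_h2(gen_fixture):
    """A predictor that ignores channel order must NOT show an order
    effect (H2) and NOT show a sampling effect for identical subsets,
    while a b0-position-sensitive stub must trigger H3."""
    subjects, sets = gen_fixture

    def order_invariant(channels, subject):
        # symmetric in the six direction channels
        fa = np.abs(channels[2:8]).mean(axis=0)
        return fa / (fa.max() + 1e-9)

    res = run_generalisation(order_invariant, subjects, sets)
    assert all(not r.significant for r in res.h2), "false order effect"

    # sanity on the result table
    counts = res.table.groupby("set")["fa_mae"].count()
    assert counts["LAR_KS"] == 3
    assert counts["LAR_Random"] == 30
    assert counts["LAR_Shuffled"] == 150
    assert counts["LAR_B0"] == 30


def test_harness_b0_sensitive_stub_triggers_h3(gen_fixture):
    subjects, sets = gen_fixture

    def b0_sensitive(channels, subject):
        # blows up when a direction channel duplicates the b0 channel
        dup = min(
            float(np.abs(channels[2 + i] - channels[1]).mean()) for i in range(6)
        )
        fa = np.abs(channels[2:8]).mean(axis=0)
        fa = fa / (fa.max() + 1e-9)
        return fa + (10.0 if dup < 1e-6 else 0.0)

    res = run_generalisation(b0_sensitive, subjects, sets)
    assert all(r.significant for r in res.h3), "b0 effect missed"
    assert all(r.test == "Mann-Whitney U" for r in res.h3)


def test_harness_resolves_order_sensitivity_in_the_table(gen_fixture):
    """Channel permutations leave an order-invariant stub's errors
    unchanged but move an order-sensitive stub's errors: the shuffled
    set genuinely probes order dependence."""
    subjects, sets = gen_fixture
    rng = np.random.default_rng(0)
    weights = rng.random(6) * 2.0  # asymmetric channel weighting

    def order_sensitive(channels, subject):
        fa = np.abs(np.tensordot(weights, channels[2:8], axes=1))
        return fa / (fa.max() + 1e-9)

    def order_invariant(channels, subject):
        fa = np.abs(channels[2:8]).mean(axis=0)
        return fa / (fa.max() + 1e-9)

    for stub, expect_moved in ((order_sensitive, True), (order_invariant, False)):
        res = run_generalisation(stub, subjects, sets)
        t = res.table[res.table["subject"] == subjects[0].name]
        rand = t[t["set"] == "LAR_Random"].sort_values("input")["fa_mae"].to_numpy()
        shuf = t[t["set"] == "LAR_Shuffled"].sort_values("input")["fa_mae"].to_numpy()
        # shuffled input 5*r + j permutes random input r
        parents = np.repeat(rand, 5)
        moved = np.abs(shuf - parents) > 1e-12
        assert moved.any() == expect_moved


def test_run_generalisation_summary_and_alpha(gen_fixture):
    subjects, sets = gen_fixture

    def stub(channels, subject):
        fa = np.abs(channels[2:8]).mean(axis=0)
        return fa / (fa.max() + 1e-9)

    res = run_generalisation(stub, subjects, sets, alpha=0.01, n_comparisons=20)
    summary = res.summary()
    for h in ("H1", "H2", "H3"):
        assert summary[h]["n_subjects"] == 3
        assert summary[h]["corrected_alpha"] == pytest.approx(0.01 / 20)


def test_run_generalisation_requires_matching_lengths(gen_fixture):
    subjects, sets = gen_fixture
    with pytest.raises(ValueError):
        run_generalisation(lambda c, s: s.reference_fa, subjects, sets[:1])
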