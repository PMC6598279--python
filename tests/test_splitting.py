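import numpy as np
import pytest
from scipy import stats

from blocksurv import (
    BlockedDataset,
    BlocksurvError,
    BlockStructure,
    CandidateSet,
    SurvivalOutcome,
    augment_mandatory_block,
    best_weighted_split,
    draw_split_point,
    logrank_statistic,
    sample_candidates_per_block,
    sample_candidates_standard,
    sample_candidates_varprob,
    select_block_randomblock,
    select_blocks_blockforest,
)


from _oracles import logrank_oracle


# ---------------------------------------------------------------------------
# log-rank statistic
# ---------------------------------------------------------------------------


def test_logrank_identical_groups_is_zero():
    assert logrank_statistic([1, 2], [1, 1], [1, 2], [1, 1]) == pytest.approx(0.0)


def test_logrank_matches_hand_coded_oracle():
    tl, sl = [1.0, 2.0], [1, 1]
    tr, sr = [3.0, 4.0], [1, 1]
    got = logrank_statistic(tl, sl, tr, sr)
    assert got == pytest.approx(logrank_oracle(tl, sl, tr, sr), abs=1e-12)


def test_logrank_all_censored_inadmissible():
    assert logrank_statistic([1, 2], [0, 0], [3, 4], [0, 0]) is None


@pytest.mark.parametrize("seed", range(5))
def test_logrank_random_samples_match_oracle_with_ties(seed):
    rng = np.random.default_rng(seed)
    nl, nr = rng.integers(2, 12, size=2)
    tl = rng.integers(1, 6, size=nl).astype(float)
    tr = rng.integers(1, 6, size=nr).astype(float)
    sl = rng.integers(0, 2, size=nl)
    sr = rng.integers(0, 2, size=nr)
    got = logrank_statistic(tl, sl, tr, sr)
    want = logrank_oracle(tl, sl, tr, sr)
    if want is None:
        assert got is None
    else:
        assert got == pytest.approx(want, abs=1e-10)


def test_logrank_symmetry_and_time_scale_invariance():
    rng = np.random.default_rng(4)
    tl = rng.exponential(1, 8) + 0.1
    tr = rng.exponential(2, 6) + 0.1
    sl = rng.integers(0, 2, 8)
    sr = rng.integers(0, 2, 6)
    a = logrank_statistic(tl, sl, tr, sr)
    assert a == pytest.approx(logrank_statistic(tr, sr, tl, sl), abs=1e-12)
    assert a == pytest.approx(logrank_statistic(7.3 * tl, sl, 7.3 * tr, sr), abs=1e-12)


def test_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(9)
    tl = rng.exponential(1, 30) + 0.1
    tr = rng.exponential(2, 25) + 0.1
    sl = rng.integers(0, 2, 30)
    sr = rng.integers(0, 2, 25)
    ours = logrank_statistic(tl, sl, tr, sr)
    ref = logrank_test(tl, tr, event_observed_A=sl, event_observed_B=sr)
    assert ours == pytest.approx(ref.test_statistic, rel=1e-9)


# ---------------------------------------------------------------------------
# split point drawing
# ---------------------------------------------------------------------------


def test_split_point_constant_variable_returns_none(rng):
    assert draw_split_point([0.0, 0.0, 0.0], rng) is None


def test_split_point_inside_open_interval(rng):
    for _ in range(100):
        thr = draw_split_point([0.0, 1.0], rng)
        assert 0.0 < thr < 1.0


def test_split_point_distribution_uniform(rng):
    values = rng.uniform(2.0, 5.0, size=40)
    lo, hi = values.min(), values.max()
    draws = np.array([draw_split_point(values, rng) for _ in range(20000)])
    u = (draws - lo) / (hi - lo)
    assert stats.kstest(u, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------


def test_standard_sampling_exhaustive_and_capped(rng):
    s = BlockStructure.from_sizes([5])
    c = sample_candidates_standard(s, 5, rng)
    assert sorted(c.variables) == [0, 1, 2, 3, 4]
    s3 = BlockStructure.from_sizes([3])
    with pytest.warns(UserWarning, match="capped"):
        c = sample_candidates_standard(s3, 7, rng)
    assert sorted(c.variables) == [0, 1, 2]


def test_standard_sampling_uniform_inclusion(rng):
    s = BlockStructure.from_sizes([20])
    counts = np.zeros(20)
    n_draws = 4000
    for _ in range(n_draws):
        counts[sample_candidates_standard(s, 4, rng).variables] += 1
    expect = n_draws * 4 / 20
    sigma = np.sqrt(n_draws * 0.2 * 0.8)
    assert np.all(np.abs(counts - expect) < 4 * sigma)


def test_varprob_block_frequency(rng):
    # v = (0.055, 0.005) on p = (10, 90): block-1 single-draw probability 0.55
    s = BlockStructure.from_sizes([10, 90])
    hits = 0
    n_draws = 3000
    for _ in range(n_draws):
        c = sample_candidates_varprob(s, [0.055, 0.005], mtry=1, rng=rng)
        hits += int(c.blocks[0] == 0)
    sigma = np.sqrt(0.55 * 0.45 / n_draws)
    assert abs(hits / n_draws - 0.55) < 4 * sigma


def test_varprob_zero_probability_block_never_sampled(rng):
    s = BlockStructure.from_sizes([4, 4])
    for _ in range(50):
        c = sample_candidates_varprob(s, [0.25, 0.0], mtry=3, rng=rng)
        assert np.all(c.blocks == 0)


def test_per_block_counts_forced(rng):
    s = BlockStructure.from_sizes([4, 9])
    c = sample_candidates_per_block(s, rng)
    assert (c.blocks == 0).sum() == 2 and (c.blocks == 1).sum() == 3
    # a 1-variable block is always included
    s2 = BlockStructure.from_sizes([1, 100])
    for _ in range(20):
        c = sample_candidates_per_block(s2, rng)
        assert 0 in c.variables
    # restriction to one block
    c = sample_candidates_per_block(s, rng, selected_blocks=[1])
    assert len(c) == 3 and np.all(c.blocks == 1)


def test_randomblock_degenerate_and_deterministic():
    rng = np.random.default_rng(0)
    assert all(
        select_block_randomblock([1.0, 0.0, 0.0], rng) == 0 for _ in range(20)
    )
    a = [select_block_randomblock([0.5, 0.5], np.random.default_rng(77)) for _ in range(10)]
    b = [select_block_randomblock([0.5, 0.5], np.random.default_rng(77)) for _ in range(10)]
    assert a == b


def test_blockforest_single_block_forced(rng):
    for _ in range(20):
        assert list(select_blocks_blockforest(1, rng)) == [0]


def test_blockforest_subsets_nonempty(rng):
    for _ in range(300):
        sel = select_blocks_blockforest(4, rng)
        assert 1 <= sel.size <= 4


# ---------------------------------------------------------------------------
# best weighted split
# ---------------------------------------------------------------------------


def _binary_split_data():
    """Two binary candidate variables with deterministic partitions, so raw
    criteria are reproducible regardless of the random threshold."""
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    status = np.ones(8, dtype=int)
    # variable 0 separates early vs late deaths perfectly; variable 1 poorly
    x0 = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    x1 = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
    X = np.column_stack([x0, x1])
    structure = BlockStructure.from_sizes([1, 1])
    data = BlockedDataset(X, SurvivalOutcome(time, status), structure)
    raws = {}
    for j in (0, 1):
        left = X[:, j] <= 0.5
        raws[j] = (time[left], status[left], time[~left], status[~left])
    return data, raws


def test_best_split_weights_can_flip_the_winner(rng):
    data, groups = _binary_split_data()
    raw0 = logrank_oracle(*groups[0])
    raw1 = logrank_oracle(*groups[1])
    assert raw0 > raw1  # variable 0 separates better
    cand = CandidateSet(np.array([0, 1]), np.array([0, 1]))
    rows = np.arange(8)
    unweighted = best_weighted_split(data, rows, cand, None, rng)
    assert unweighted.variable == 0
    assert unweighted.raw_criterion == pytest.approx(raw0, abs=1e-10)
    # demote block 0 enough that block 1 wins on the weighted criterion
    w = [0.9 * raw1 / raw0, 1.0]
    weighted = best_weighted_split(data, rows, cand, w, rng)
    assert weighted.variable == 1
    assert weighted.raw_criterion == pytest.approx(raw1, abs=1e-10)
    assert weighted.weighted_criterion == pytest.approx(raw1, abs=1e-10)


def test_best_split_identity_weights_match_unweighted_stream():
    data, _ = _binary_split_data()
    cand = CandidateSet(np.array([0, 1]), np.array([0, 1]))
    rows = np.arange(8)
    a = best_weighted_split(data, rows, cand, None, np.random.default_rng(5))
    b = best_weighted_split(data, rows, cand, [1.0, 1.0], np.random.default_rng(5))
    assert a == b


def test_best_split_constant_candidates_return_none(rng):
    time = np.array([1.0, 2.0, 3.0, 4.0])
    data = BlockedDataset(
        np.ones((4, 2)),
        SurvivalOutcome(time, np.array([1, 1, 1, 1])),
        BlockStructure.from_sizes([2]),
    )
    cand = CandidateSet(np.array([0, 1]), np.array([0, 0]))
    assert best_weighted_split(data, np.arange(4), cand, None, rng) is None


def test_best_split_empty_candidates_return_none(rng):
    data, _ = _binary_split_data()
    cand = CandidateSet(np.array([], dtype=int), np.array([], dtype=int))
    assert best_weighted_split(data, np.arange(8), cand, None, rng) is None


def test_best_split_raw_matches_bruteforce_oracle(rng):
    """The winner's raw criterion equals a re-evaluation of its partition."""
    n = 40
    time = rng.exponential(1, n) + 0.1
    status = rng.integers(0, 2, n)
    status[0] = 1
    X = (rng.uniform(size=(n, 6)) > 0.5).astype(float)  # binary => threshold-free
    data = BlockedDataset(
        X, SurvivalOutcome(time, status), BlockStructure.from_sizes([3, 3])
    )
    cand = CandidateSet(np.arange(6), np.array([0, 0, 0, 1, 1, 1]))
    prop = best_weighted_split(data, np.arange(n), cand, None, rng)
    if prop is None:
        pytest.skip("no admissible split in this draw")
    left = X[:, prop.variable] <= prop.threshold
    want = logrank_oracle(time[left], status[left], time[~left], status[~left])
    assert prop.raw_criterion == pytest.approx(want, abs=1e-10)
    # ... and no other candidate's partition scores higher (binary data, so
    # the drawn threshold cannot change the partition)
    for j in range(6):
        lj = X[:, j] <= 0.5
        if lj.all() or (~lj).all():
            continue
        other = logrank_oracle(time[lj], status[lj], time[~lj], status[~lj])
        if other is not None:
            assert other <= prop.raw_criterion + 1e-10


# ---------------------------------------------------------------------------
# mandatory clinical augmentation
# ---------------------------------------------------------------------------


def test_augment_adds_all_clinical_variables():
    s = BlockStructure.from_sizes([4, 10], ["clin", "rna"], clinical_block="clin")
    cand = CandidateSet(np.array([6, 7, 8]), np.array([1, 1, 1]))
    grown = augment_mandatory_block(cand, s)
    assert len(grown) == 7
    assert set(range(4)) <= set(grown.variables)


def test_augment_deduplicates_existing_clinical_variables():
    s = BlockStructure.from_sizes([4, 10], ["clin", "rna"], clinical_block="clin")
    cand = CandidateSet(np.array([0, 2, 6]), np.array([0, 0, 1]))
    grown = augment_mandatory_block(cand, s)
    assert len(grown) == 5
    assert sorted(grown.variables) == [0, 1, 2, 3, 6]


def test_augment_requires_clinical_designation():
    s = BlockStructure.from_sizes([4, 10])
    cand = CandidateSet(np.array([5]), np.array([1]))
    with pytest.raises(BlocksurvError, match="clinical"):
        augment_mandatory_block(cand, s)
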