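import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aicmax import (
    DegenerateTaskError,
    LabeledDataset,
    aic_score,
    aic_score_multi,
    brute_force_aic,
    empirical_joint,
    greedy_select,
    label_entropy,
    rank_bits_individual,
)
from aicmax.synthetic import PlantedBit, SyntheticSpec, closed_form_singleton_aic, generate

from conftest import make_matrix, random_dataset, xor_dataset


class TestLabelEntropy:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([1, 0, 1, 0], 1.0),
            ([1, 1, 1], 0.0),
            ([0, 0, 0, 0], 0.0),
            ([1, 0, 0, 0], 0.8112781244591328),  # -1/4 log2 1/4 - 3/4 log2 3/4
        ],
    )
    def test_known_values(self, labels, expected):
        assert label_entropy(labels) == pytest.approx(expected, abs=1e-12)

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            label_entropy([])


class TestEmpiricalJoint:
    def test_bit_identical_to_labels_has_two_support_points(self):
        labels = np.array([1, 1, 0, 0, 0])
        ds = make_matrix(labels[:, None])
        dist = empirical_joint(ds, [0], labels)
        assert set(dist.joint_probs) == {((1,), 1), ((0,), 0)}
        assert dist.joint_probs[((1,), 1)] == pytest.approx(0.4)
        assert dist.joint_probs[((0,), 0)] == pytest.approx(0.6)

    def test_constant_zero_pair_collapses_to_one_pattern(self):
        m = make_matrix(np.zeros((6, 2), dtype=int))
        dist = empirical_joint(m, [0, 1], [1, 0, 1, 0, 1, 0])
        assert dist.pattern_probs == {(0, 0): 1.0}

    def test_eight_row_hand_count(self, eight_row_dataset):
        ds = eight_row_dataset
        dist = empirical_joint(ds.matrix, [0], ds.labels)
        assert dist.pattern_probs[(1,)] == pytest.approx(3 / 8)
        assert dist.joint_probs[((1,), 1)] == pytest.approx(3 / 8)
        assert dist.joint_probs[((0,), 1)] == pytest.approx(1 / 8)
        assert dist.joint_probs[((0,), 0)] == pytest.approx(4 / 8)

    def test_normalization_and_marginals_on_random_input(self, rng):
        ds = random_dataset(rng, n=40, bits=6)
        dist = empirical_joint(ds.matrix, [0, 3, 5], ds.labels)
        dist.validate()

    def test_empty_subset_is_hard_error(self, rng):
        ds = random_dataset(rng)
        with pytest.raises(ValueError):
            empirical_joint(ds.matrix, [], ds.labels)


class TestAicScore:
    def test_perfect_bit_scores_one(self):
        labels = np.array([1, 1, 1, 0, 0])
        assert aic_score(make_matrix(labels[:, None]), [0], labels) == pytest.approx(1.0)

    def test_exactly_independent_bit_scores_zero(self):
        # counts factorize exactly: within each class the bit is half on
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        bit = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        assert aic_score(make_matrix(bit[:, None]), [0], labels) == pytest.approx(0.0, abs=1e-12)

    def test_eight_row_hand_value(self, eight_row_dataset):
        ds = eight_row_dataset
        assert aic_score(ds.matrix, [0], ds.labels) == pytest.approx(
            0.5487949406953986, abs=1e-12
        )

    def test_single_class_labels_raise(self):
        with pytest.raises(DegenerateTaskError):
            aic_score(make_matrix([[0], [1]]), [0], [1, 1])

    def test_score_consistent_with_pattern_distribution(self, rng):
        ds = random_dataset(rng, n=30, bits=5)
        subset = [1, 2, 4]
        dist = empirical_joint(ds.matrix, subset, ds.labels)
        expected = dist.mutual_information() / label_entropy(ds.labels)
        assert aic_score(ds.matrix, subset, ds.labels) == pytest.approx(expected, abs=1e-12)


class TestBruteForceOracle:
    def test_matches_fast_path_on_random_draws(self, rng):
        for _ in range(60):
            ds = random_dataset(rng, n=30, bits=10)
            size = int(rng.integers(1, 9))
            subset = list(rng.choice(10, size=size, replace=False))
            assert abs(
                aic_score(ds.matrix, subset, ds.labels)
                - brute_force_aic(ds.matrix, subset, ds.labels)
            ) < 1e-10

    def test_boundary_cases(self):
        labels = np.array([1, 0, 1, 0])
        perfect = make_matrix(labels[:, None])
        assert brute_force_aic(perfect, [0], labels) == pytest.approx(1.0)
        indep = make_matrix(np.array([[1], [1], [0], [0]]))
        assert brute_force_aic(indep, [0], labels) == pytest.approx(0.0, abs=1e-12)

    def test_subset_size_limit(self, rng):
        ds = random_dataset(rng, n=10, bits=20)
        with pytest.raises(ValueError):
            brute_force_aic(ds.matrix, list(range(17)), ds.labels)


class TestMultiTask:
    def test_single_task_reduces_to_plain_score(self, rng):
        ds = random_dataset(rng)
        assert aic_score_multi([ds], [0, 1]) == pytest.approx(
            aic_score(ds.matrix, [0, 1], ds.labels)
        )

    def test_mean_of_perfect_and_independent_is_half(self):
        labels = np.array([1, 1, 0, 0])
        perfect = LabeledDataset(make_matrix(labels[:, None]), labels, "p")
        indep = LabeledDataset(
            make_matrix(np.array([[1], [0], [1], [0]])), labels, "i"
        )
        assert aic_score_multi([perfect, indep], [0]) == pytest.approx(0.5)

    def test_equals_average_of_per_task_scores(self, rng):
        tasks = [random_dataset(rng, n=25, bits=6, task_id=f"t{i}") for i in range(3)]
        subset = [0, 2]
        expected = np.mean([aic_score(t.matrix, subset, t.labels) for t in tasks])
        assert aic_score_multi(tasks, subset) == pytest.approx(expected, abs=1e-12)

    def test_missing_bit_is_hard_error(self, rng):
        a = random_dataset(rng, bits=4, task_id="a")
        b = LabeledDataset(
            make_matrix(a.matrix.values, bit_ids=[10, 11, 12, 13]), a.labels, "b"
        )
        with pytest.raises(KeyError):
            aic_score_multi([a, b], [0])


class TestRankBitsIndividual:
    def test_perfect_bit_ranks_first(self):
        labels = np.array([1, 1, 0, 0, 1, 0])
        values = np.column_stack([np.array([0, 1, 1, 0, 0, 1]), labels])
        ranked = rank_bits_individual(LabeledDataset(make_matrix(values), labels))
        assert ranked[0] == (1, pytest.approx(1.0))

    def test_constant_bits_tie_broken_by_ascending_id(self):
        m = make_matrix(np.zeros((6, 4), dtype=int), bit_ids=[9, 3, 7, 1])
        ranked = rank_bits_individual(LabeledDataset(m, np.array([1, 0, 1, 0, 1, 0])))
        assert [b for b, _ in ranked] == [1, 3, 7, 9]
        assert all(s == 0.0 for _, s in ranked)

    def test_planted_bit_close_to_closed_form(self):
        spec = SyntheticSpec(
            n_active=5000, n_inactive=5000,
            planted_bits=[PlantedBit(0, 0.8, 0.2)], n_noise_bits=0, seed=11,
        )
        (ds,), _ = generate(spec)
        ranked = rank_bits_individual(ds)
        expected = closed_form_singleton_aic(0.8, 0.2, 0.5)
        assert ranked[0][0] == 0
        assert ranked[0][1] == pytest.approx(expected, abs=0.02)


class TestGreedySelect:
    def test_exhaustion_selects_every_bit(self, rng):
        ds = random_dataset(rng, n=20, bits=5)
        result = greedy_select(ds, k=50)
        assert sorted(result.selected) == sorted(ds.matrix.bit_ids)
        assert len(result.trajectory) == 5

    def test_xor_pair_uniquely_recovered(self):
        ds = xor_dataset()
        # independent exhaustive oracle: only {0, 1} attains score 1.0
        perfect_pairs = [
            pair
            for pair in itertools.combinations(ds.matrix.bit_ids, 2)
            if brute_force_aic(ds.matrix, list(pair), ds.labels) > 1 - 1e-12
        ]
        assert perfect_pairs == [(0, 1)]
        result = greedy_select(ds, k=2)
        assert result.selected == [0, 1]
        assert result.trajectory[-1] == pytest.approx(1.0)
        assert result.saturated_at == 1

    def test_default_k_gives_hundred_bits(self):
        spec = SyntheticSpec(
            n_active=100, n_inactive=100,
            planted_bits=[PlantedBit(i, 0.7, 0.3) for i in range(10)],
            n_noise_bits=110, p_noise=0.3, seed=5,
        )
        (ds,), _ = generate(spec)
        assert ds.matrix.n_bits >= 100
        result = greedy_select(ds)
        assert len(result.selected) == 100

    def test_k_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            greedy_select(random_dataset(rng), k=0)

    def test_trajectory_non_decreasing_and_bounded(self, rng):
        ds = random_dataset(rng, n=40, bits=15)
        result = greedy_select(ds, k=15)
        traj = np.array(result.trajectory)
        assert (np.diff(traj) >= -1e-12).all()
        assert ((traj >= 0) & (traj <= 1)).all()

    def test_saturation_falls_through_to_tie_break(self):
        # a perfect bit saturates at step 1; afterwards every candidate
        # ties at 1.0 and selection follows singleton score then bit id
        labels = np.array([1, 1, 1, 0, 0, 0])
        informative = np.array([1, 1, 0, 0, 0, 0])  # imperfect but informative
        values = np.column_stack([labels, informative, np.zeros(6, dtype=int)])
        ds = LabeledDataset(make_matrix(values, bit_ids=[5, 1, 0]), labels)
        result = greedy_select(ds, k=3)
        assert result.selected == [5, 1, 0]
        assert result.trajectory == [1.0, 1.0, 1.0]
        assert result.saturated_at == 0

    def test_multi_task_selection_shares_bit_universe(self, rng):
        tasks = [random_dataset(rng, n=30, bits=8, task_id=f"t{i}") for i in range(2)]
        result = greedy_select(tasks, k=4)
        assert len(result.selected) == 4
        assert result.task_ids == ["t0", "t1"]


# ---------------------------------------------------------------------------
# property-based invariants

binary_tasks = st.integers(4, 24).flatmap(
    lambda n: st.tuples(
        st.lists(
            st.lists(st.integers(0, 1), min_size=4, max_size=4),
            min_size=n, max_size=n,
        ),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda y: 0 < sum(y) < len(y)
        ),
    )
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(binary_tasks)
def test_score_in_unit_interval_and_label_symmetric(data):
    """0 ≤ AIC ≤ 1, and flipping every label leaves the score unchanged."""
    rows, labels = data
    m = make_matrix(np.array(rows))
    y = np.array(labels)
    score = aic_score(m, [0, 1, 2], y)
    assert 0.0 <= score <= 1.0
    assert aic_score(m, [0, 1, 2], 1 - y) == pytest.approx(score, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(binary_tasks, st.permutations([0, 1, 2, 3]))
def test_bit_order_and_duplication_invariance(data, perm):
    """Permuting subset order or re-adding a selected bit never changes the score."""
    rows, labels = data
    m = make_matrix(np.array(rows))
    y = np.array(labels)
    base = aic_score(m, [0, 1, 2, 3], y)
    assert aic_score(m, perm, y) == pytest.approx(base, abs=1e-12)
    dup = make_matrix(np.column_stack([np.array(rows), np.array(rows)[:, 0]]))
    assert aic_score(dup, [0, 1, 2, 3, 4], y) == pytest.approx(base, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(binary_tasks)
def test_adding_a_bit_never_decreases_the_score(data):
    """Empirical MI is monotone under subset growth (ML estimates)."""
    rows, labels = data
    m = make_matrix(np.array(rows))
    y = np.array(labels)
    for subset in ([0], [0, 1], [0, 1, 2]):
        smaller = aic_score(m, subset, y)
        for extra in range(4):
            if extra not in subset:
                larger = aic_score(m, subset + [extra], y)
                assert larger >= smaller - 1e-12
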