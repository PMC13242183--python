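import numpy as np
import pytest

from conftest import make_labeled
from omicsfuse.bench import make_fold_plan
from omicsfuse.relieff import (
    ReliefConfig,
    cross_omics_intersection,
    diff_matrix,
    rank_and_aggregate_folds,
    relieff_weights,
    run_fold_selection,
    select_top_n,
    stable_gene_set,
    union_gene_set,
)
from reference_relieff import brute_force_relieff


class TestDiff:
    def test_range_normalized_absolute_difference(self):
        X = np.array([[0.3, 5.0], [0.7, 5.0], [1.3, 5.0]])
        Xn = diff_matrix(X)
        assert abs(Xn[0, 0] - Xn[1, 0]) == pytest.approx(0.4)
        assert abs(Xn[1, 0] - Xn[1, 0]) == 0.0
        assert np.all(Xn[:, 1] == 0.0)  # zero-range attribute contributes 0


class TestWeights:
    def test_four_sample_micro_example(self):
        """Two tight same-class pairs far apart on A, B constant: every hit
        diff is 0.1, miss diffs are 0.9/0.8/0.8/0.9 -> W[A] = 0.75 exactly."""
        X = np.array([[0.0, 3.0], [0.1, 3.0], [0.9, 3.0], [1.0, 3.0]])
        y = np.array([0, 0, 1, 1])
        w = relieff_weights(X, y, ReliefConfig(k_neighbors=1))
        np.testing.assert_allclose(w.weights, [0.75, 0.0], atol=1e-15)

    def test_perfectly_separating_binary_feature(self):
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        w = relieff_weights(X, y, ReliefConfig(k_neighbors=1))
        assert w.weights[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("k_neighbors", [1, 3, 5])
    def test_matches_bruteforce_reference(self, k_neighbors):
        rng = np.random.default_rng(42 + k_neighbors)
        for _ in range(10):
            n = int(rng.integers(2 * (k_neighbors + 1), 30))
            m = int(rng.integers(2, 12))
            X = rng.normal(size=(n, m))
            y = np.array([0] * (n // 2) + [1] * (n - n // 2))
            rng.shuffle(y)
            if min((y == 0).sum(), (y == 1).sum()) < k_neighbors + 1:
                continue
            w = relieff_weights(X, y, ReliefConfig(k_neighbors=k_neighbors))
            ref = brute_force_relieff(X, y, k_neighbors)
            np.testing.assert_allclose(w.weights, ref, atol=1e-10)

    def test_permuted_labels_give_near_zero_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 50))
        y = rng.permutation([0] * 100 + [1] * 100)
        w = relieff_weights(X, y, ReliefConfig(k_neighbors=10))
        # null weights scatter around 0; 3 sd of the empirical null spread
        assert np.all(np.abs(w.weights) < 3 * np.std(w.weights) + 1e-12)
        assert abs(w.weights.mean()) < 0.01

    def test_weights_bounded_and_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 8))
        y = np.array([0, 1] * 20)
        a = relieff_weights(X, y, ReliefConfig(k_neighbors=3))
        b = relieff_weights(X, y, ReliefConfig(k_neighbors=3))
        np.testing.assert_array_equal(a.weights, b.weights)
        assert np.all(a.weights >= -1.0) and np.all(a.weights <= 1.0)

    def test_signal_weight_grows_with_class_separation(self):
        """Mean weight of a single shifted-Gaussian feature increases with
        effect size (averaged over seeds)."""
        means = []
        for effect in (0.5, 1.5, 3.0):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                x = rng.normal(size=(60, 1))
                y = np.array([0] * 30 + [1] * 30)
                x[y == 1] += effect
                vals.append(relieff_weights(x, y, ReliefConfig(k_neighbors=5)).weights[0])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_oversized_k_clipped_with_warning(self):
        X = np.random.default_rng(2).normal(size=(8, 3))
        y = np.array([0] * 4 + [1] * 4)
        with pytest.warns(UserWarning, match="clipping"):
            relieff_weights(X, y, ReliefConfig(k_neighbors=100))

    def test_class_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            relieff_weights(np.zeros((3, 2)), np.array([0, 0, 1]), ReliefConfig(k_neighbors=1))


@pytest.fixture(scope="module")
def fold_cohort():
    return make_labeled(15, 15, 12, effect=2.0, seed=3)


class TestFoldSelection:
    def test_one_list_per_modality_per_fold(self, fold_cohort):
        cohort = fold_cohort
        plan = make_fold_plan(cohort.common_sample_ids, cohort.labels, 5, 1)
        lists = run_fold_selection(cohort, plan, ReliefConfig(k_neighbors=3))
        assert len(lists["RNA"]) == 5 and len(lists["CNV"]) == 5

    def test_validation_rows_never_influence_weights(self, fold_cohort):
        cohort = fold_cohort
        """Poisoning every validation row with huge sentinels leaves the
        per-fold train-split weights bit-identical."""
        plan = make_fold_plan(cohort.common_sample_ids, cohort.labels, 3, 2)
        clean = run_fold_selection(cohort, plan, ReliefConfig(k_neighbors=3))
        import copy

        poisoned = copy.deepcopy(cohort)
        pos = {s: i for i, s in enumerate(cohort.common_sample_ids)}
        for fold_i, (_, val_ids) in enumerate(plan.folds):
            if fold_i == 0:
                rows = [pos[s] for s in val_ids]
                poisoned.rna.values[rows] = 1e9
                poisoned.cnv.values[rows] = -1e9
        # fold 0's train split excludes exactly the poisoned rows
        dirty = run_fold_selection(poisoned, plan, ReliefConfig(k_neighbors=3))
        np.testing.assert_array_equal(clean["RNA"][0].weights, dirty["RNA"][0].weights)
        np.testing.assert_array_equal(clean["CNV"][0].weights, dirty["CNV"][0].weights)


class TestAggregation:
    def make_list(self, weights, fold):
        from omicsfuse.relieff import FeatureImportanceList

        return FeatureImportanceList(list(weights), np.array(list(weights.values())), "RNA", fold, 0)

    def test_cumulative_sum_and_reordering(self):
        l1 = self.make_list({"g1": 0.2, "g2": 0.1}, 0)
        l2 = self.make_list({"g1": 0.1, "g2": 0.3}, 1)
        ranked = rank_and_aggregate_folds([l1, l2])
        assert ranked == [("g2", pytest.approx(0.4)), ("g1", pytest.approx(0.3))]

    def test_single_fold_preserves_order(self):
        l1 = self.make_list({"a": 0.5, "b": 0.9, "c": 0.1}, 0)
        assert [g for g, _ in rank_and_aggregate_folds([l1])] == ["b", "a", "c"]

    def test_score_ties_break_lexicographically(self):
        l1 = self.make_list({"gB": 0.5, "gA": 0.5, "gC": 0.9}, 0)
        assert [g for g, _ in rank_and_aggregate_folds([l1])] == ["gC", "gA", "gB"]

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            rank_and_aggregate_folds(
                [self.make_list({"a": 0.1}, 0), self.make_list({"b": 0.1}, 1)]
            )


class TestSetChain:
    def test_select_top_n_edges(self):
        ranked = [("a", 3.0), ("b", 2.0), ("c", 1.0)]
        assert select_top_n(ranked, 3) == {"a", "b", "c"}
        assert select_top_n(ranked, 0) == frozenset()
        with pytest.raises(ValueError):
            select_top_n(ranked, 4)

    def test_stable_set_identity_and_disjoint(self):
        s = frozenset("abcde")
        assert stable_gene_set([s] * 5) == s
        assert stable_gene_set([frozenset("ab"), frozenset("cd")]) == frozenset()

    def test_cross_omics_set_laws(self):
        a, b = frozenset("abc"), frozenset("bcd")
        inter = cross_omics_intersection(a, b)
        union = union_gene_set(a, b)
        assert inter == {"b", "c"}
        assert union == {"a", "b", "c", "d"}
        assert cross_omics_intersection(frozenset("ab"), frozenset("cd")) == frozenset()
        assert cross_omics_intersection(frozenset("ab"), frozenset("abc")) == {"a", "b"}
        assert len(union) >= max(len(a), len(b))
        # chain sizes are non-increasing
        assert len(inter) <= min(len(a), len(b))
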