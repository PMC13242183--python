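import itertools
import json

import numpy as np
import pytest

from conftest import make_labeled
from omicsfuse.bench import ClassifierSpec
from omicsfuse.evaluation import (
    ConfusionCounts,
    MetricsEntry,
    aggregate_over_seeds,
    auroc,
    classification_metrics,
    confusion_counts,
    evaluate_selected_genes,
    mann_whitney_compare,
    pairwise_pearson,
    render_report,
)
from omicsfuse.preprocess import OmicsMatrix


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion_counts([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_fully_wrong(self):
        c = confusion_counts([1, 0], [0, 1])
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 1, 1, 0)

    def test_all_negative_predictions(self):
        c = confusion_counts([1, 1, 0], [0, 0, 0])
        assert (c.tp, c.fn, c.tn, c.fp) == (0, 2, 1, 0)

    def test_label_outside_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([0, 2], [0, 1])


class TestMetrics:
    def test_hand_computed_example(self):
        m = classification_metrics(ConfusionCounts(tp=9, fp=1, tn=8, fn=2))
        assert m.accuracy == pytest.approx(0.85)
        assert m.precision_ppv == pytest.approx(0.9)
        assert m.recall_sensitivity == pytest.approx(9 / 11, abs=1e-4)
        assert m.specificity == pytest.approx(8 / 9, abs=1e-4)
        assert m.f1 == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11), abs=1e-4)
        assert m.npv == pytest.approx(0.8)
        assert m.undefined == ()

    def test_perfect_counts_all_ones(self):
        m = classification_metrics(ConfusionCounts(5, 0, 5, 0))
        assert all(getattr(m, n) == 1.0 for n in ("accuracy", "precision_ppv", "recall_sensitivity", "specificity", "f1", "npv"))

    def test_zero_denominator_flagged_not_dropped(self):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert m.precision_ppv == 0.0 and "precision_ppv" in m.undefined
        assert m.accuracy == pytest.approx(0.6)

    def test_positive_class_swap_symmetry(self):
        """Relabeling the positive class swaps precision<->NPV and
        recall<->specificity."""
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        p = np.array([1, 0, 0, 1, 1, 0, 1, 0])
        m1 = classification_metrics(confusion_counts(y, p, positive_class=1))
        m0 = classification_metrics(confusion_counts(y, p, positive_class=0))
        assert m1.precision_ppv == pytest.approx(m0.npv)
        assert m1.recall_sensitivity == pytest.approx(m0.specificity)
        assert m1.accuracy == pytest.approx(m0.accuracy)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2]) == 1.0

    def test_three_of_four_concordant_pairs(self):
        assert auroc([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2]) == 0.75

    def test_all_ties_give_half(self):
        assert auroc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1], [0.2, 0.3])

    def test_equivalence_with_sklearn_on_random_instances(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(size=n), 1)  # rounded -> frequent ties
            assert auroc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestAggregate:
    def test_identical_entries_sd_zero(self):
        e = MetricsEntry(accuracy=0.9, auroc=0.95, precision_ppv=0.8,
                         recall_sensitivity=0.7, specificity=0.6, f1=0.75, npv=0.85)
        rep = aggregate_over_seeds({1: e, 2: e, 3: e})
        assert rep.mean["accuracy"] == pytest.approx(0.9)
        assert all(v < 1e-12 for v in rep.sd.values())

    def test_population_sd_hand_example(self):
        entries = {
            i: MetricsEntry(accuracy=a, auroc=0, precision_ppv=0,
                            recall_sensitivity=0, specificity=0, f1=0, npv=0)
            for i, a in enumerate([0.9, 0.9, 0.9, 0.9, 1.0])
        }
        rep = aggregate_over_seeds(entries)
        assert rep.mean["accuracy"] == pytest.approx(0.92)
        assert rep.sd["accuracy"] == pytest.approx(0.04)

    def test_mean_within_input_range(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=6)
        entries = {i: MetricsEntry(accuracy=v, auroc=0, precision_ppv=0,
                                   recall_sensitivity=0, specificity=0, f1=0, npv=0)
                   for i, v in enumerate(vals)}
        rep = aggregate_over_seeds(entries)
        assert vals.min() <= rep.mean["accuracy"] <= vals.max()


def enumerate_exact_p(a, b):
    """Exhaustive two-sided Mann-Whitney p: enumerate all C(nA+nB, nA)
    assignments of the pooled values and count |U - mean| >= observed."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in group_a for y in group_b
        )

    u_obs = u_stat(a, b)
    mu = n_a * len(b) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(ga, gb)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_groups(self):
        r = mann_whitney_compare([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0.0
        assert r.effect_size == pytest.approx(1.0)
        assert r.p_value == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_identical_groups_zero_effect(self):
        r = mann_whitney_compare([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert r.effect_size == pytest.approx(0.0)

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = list(np.round(rng.normal(size=rng.integers(3, 6)), 2))
            b = list(np.round(rng.normal(size=rng.integers(3, 6)), 2))
            if len(set(a + b)) != len(a + b):
                continue  # exact method assumes no ties
            r = mann_whitney_compare(a, b)
            assert r.p_value == pytest.approx(enumerate_exact_p(a, b), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_compare([], [1.0])


class TestPearson:
    def make_matrix(self, values, genes):
        return OmicsMatrix("RNA", [f"s{i}" for i in range(len(values))], genes, values)

    def test_self_and_anticorrelation(self):
        g1 = np.arange(10.0)
        m = self.make_matrix(np.column_stack([g1, -g1]), ["g1", "g2"])
        corr = pairwise_pearson(m, ["g1", "g2"])
        assert corr[0, 0] == 1.0
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 5))
        genes = [f"g{i}" for i in range(5)]
        corr = pairwise_pearson(self.make_matrix(X, genes), genes)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        expected = ((X - mu).T @ (X - mu) / len(X)) / np.outer(sd, sd)
        np.testing.assert_allclose(corr, expected, atol=1e-12)
        np.testing.assert_allclose(corr, corr.T, atol=0)

    def test_constant_gene_reported_zero(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        corr = pairwise_pearson(self.make_matrix(X, ["g1", "g2"]), ["g1", "g2"])
        assert corr[0, 1] == 0.0 and corr[1, 1] == 1.0

    def test_unknown_gene_rejected(self):
        m = self.make_matrix(np.zeros((3, 1)), ["g1"])
        with pytest.raises(KeyError):
            pairwise_pearson(m, ["nope"])


@pytest.fixture(scope="module")
def eval_cohort():
    return make_labeled(15, 15, 12, effect=2.5, seed=6)


class TestSelectedGeneEvaluation:
    def test_full_gene_set_reproduces_unrestricted_run(self, eval_cohort):
        cohort = eval_cohort
        spec = ClassifierSpec("gradient_boosting")
        full = evaluate_selected_genes(cohort, cohort.rna.gene_ids, spec, k=3, seeds=[1, 2])
        again = evaluate_selected_genes(cohort, cohort.rna.gene_ids, spec, k=3, seeds=[1, 2])
        for approach in full:
            assert full[approach].mean == again[approach].mean

    def test_planted_panel_fusion_competitive(self, eval_cohort):
        cohort = eval_cohort
        spec = ClassifierSpec("gradient_boosting")
        panel = cohort.rna.gene_ids[:3]  # the informative genes
        rep = evaluate_selected_genes(cohort, panel, spec, k=3, seeds=[1, 2, 3])
        assert rep["fused"].mean["accuracy"] >= 0.5
        wins = sum(
            rep["fused"].per_seed[s].accuracy
            >= max(rep["RNA"].per_seed[s].accuracy, rep["CNV"].per_seed[s].accuracy)
            for s in rep["fused"].per_seed
        )
        assert wins >= 1

    def test_empty_and_missing_gene_sets_rejected(self, eval_cohort):
        cohort = eval_cohort
        spec = ClassifierSpec("gradient_boosting")
        with pytest.raises(ValueError):
            evaluate_selected_genes(cohort, [], spec)
        with pytest.raises(KeyError, match="NOPE"):
            evaluate_selected_genes(cohort, ["NOPE"], spec, k=2, seeds=[1])


class TestReport:
    def test_round_trip_and_provenance(self):
        e = MetricsEntry(accuracy=0.91234, auroc=0.95, precision_ppv=0.8,
                         recall_sensitivity=0.7, specificity=0.6, f1=0.75, npv=0.85)
        rep = aggregate_over_seeds({1: e, 2: e})
        text, machine = render_report({"RNA": rep}, config={"seeds": [1, 2], "k": 5})
        assert "0.912±0.000" in text
        assert machine["config"]["seeds"] == [1, 2]
        assert len(machine["config_hash"]) == 12
        parsed = json.loads(json.dumps(machine))
        assert parsed["approaches"]["RNA"]["mean"]["accuracy"] == pytest.approx(0.91234)
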