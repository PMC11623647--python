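"""Metrics vs brute-force oracles; binned fit and overlap."""

import numpy as np
import pytest

import thriftyshm as ts
from thriftyshm.evaluation import (
    BinaryPredictionSet,
    BinnedFit,
    auprc,
    auroc,
    binned_fit,
    heldout_loglik,
    overlap,
    r_precision,
    substitution_accuracy,
)


# --- independent oracles ---------------------------------------------------

def auroc_oracle(scores, labels):
    """Exhaustive positive-negative pair counting; ties count 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def auprc_oracle(scores, labels):
    """Average precision by explicit descending-threshold sweep."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    total_pos = y.sum()
    ap = 0.0
    prev_recall = 0.0
    # thresholds at distinct scores
    for thr in np.unique(s)[::-1]:
        taken = s >= thr
        tp = y[taken].sum()
        precision = tp / taken.sum()
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def r_precision_oracle(scores, labels):
    R = labels.sum()
    top = np.argsort(-scores, kind="stable")[:R]
    return labels[top].mean()


def random_instances(n_instances=200, max_n=50, seed=42):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = rng.integers(3, max_n + 1)
        scores = np.round(rng.random(n), rng.integers(1, 4))  # induce ties
        labels = rng.random(n) < rng.uniform(0.1, 0.6)
        if labels.all() or not labels.any():
            labels[0] = True
            labels[-1] = False
        yield BinaryPredictionSet(scores, labels)


class TestMetricOracles:
    def test_auroc_matches_pair_counting_on_200_instances(self):
        for preds in random_instances():
            assert auroc(preds) == pytest.approx(
                auroc_oracle(preds.scores, preds.labels), abs=1e-12)

    def test_auprc_matches_threshold_sweep_on_200_instances(self):
        for preds in random_instances():
            assert auprc(preds) == pytest.approx(
                auprc_oracle(preds.scores, preds.labels), abs=1e-12)

    def test_r_precision_matches_top_r_selection_on_200_instances(self):
        for preds in random_instances():
            assert r_precision(preds) == pytest.approx(
                r_precision_oracle(preds.scores, preds.labels), abs=1e-12)


class TestAUROC:
    def test_worked_example(self):
        preds = BinaryPredictionSet([0.9, 0.4, 0.35, 0.8], [1, 0, 1, 0])
        assert auroc(preds) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert auroc(BinaryPredictionSet([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_all_ties_is_half(self):
        assert auroc(BinaryPredictionSet([0.5] * 6, [1, 0, 1, 0, 0, 0])) == 0.5

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(100)
        labels = rng.random(100) < 0.2
        labels[0] = True
        labels[1] = False
        a = auroc(BinaryPredictionSet(scores, labels))
        b = auroc(BinaryPredictionSet(np.exp(5 * scores) + 3, labels))
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(BinaryPredictionSet([0.1, 0.2], [1, 1]))


class TestAUPRC:
    def test_worked_example(self):
        preds = BinaryPredictionSet([0.9, 0.8, 0.1], [1, 0, 1])
        assert auprc(preds) == pytest.approx(0.833333, abs=1e-6)

    def test_perfect_ranking(self):
        assert auprc(BinaryPredictionSet([0.9, 0.8, 0.1], [1, 1, 0])) == 1.0

    def test_random_scores_approach_rho(self, rng):
        n = 200_000
        labels = rng.random(n) < 0.05
        scores = rng.random(n)
        preds = BinaryPredictionSet(scores, labels)
        assert auprc(preds) == pytest.approx(preds.rho, rel=0.1)


class TestRPrecision:
    def test_worked_example(self):
        # ranking: mut, non, mut, non with R=2 -> 1 true in top 2
        preds = BinaryPredictionSet([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert r_precision(preds) == 0.5

    def test_perfect_ranking(self):
        assert r_precision(BinaryPredictionSet([0.9, 0.8, 0.1], [1, 1, 0])) == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            r_precision(BinaryPredictionSet([0.5, 0.4], [0, 0]))


class TestSubstitutionAccuracy:
    def test_single_site_correct(self):
        assert substitution_accuracy(np.array([[0, 0.7, 0.2, 0.1]]), [1]) == 1.0

    def test_chance_level_with_uniform_csp(self, rng):
        n = 30_000
        rows = np.tile([0.0, 1 / 3, 1 / 3, 1 / 3], (n, 1))
        child = rng.integers(1, 4, size=n)  # parent is base 0 everywhere
        acc = substitution_accuracy(rows, child)
        # argmax ties break to base C deterministically
        assert acc == pytest.approx(1 / 3, rel=0.05)

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            substitution_accuracy(np.empty((0, 4)), [])


class TestBinnedFitAndOverlap:
    def test_overlap_worked_example(self):
        fit = BinnedFit(np.array([0., 1., 2.]), np.array([2., 2.]), np.array([1., 3.]))
        assert overlap(fit) == pytest.approx(0.75)

    def test_identical_histograms_give_one(self):
        fit = BinnedFit(np.arange(4.), np.array([1., 2., 3.]), np.array([1., 2., 3.]))
        assert overlap(fit) == 1.0

    def test_disjoint_support_gives_zero(self):
        fit = BinnedFit(np.arange(3.), np.array([2., 0.]), np.array([0., 2.]))
        assert overlap(fit) == 0.0

    def test_overlap_symmetric(self, rng):
        o = rng.poisson(5, size=10).astype(float)
        e = rng.poisson(5, size=10).astype(float)
        f1 = BinnedFit(np.arange(11.), o, e)
        f2 = BinnedFit(np.arange(11.), e, o)
        assert overlap(f1) == overlap(f2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            overlap(BinnedFit(np.arange(3.), np.zeros(2), np.zeros(2)))

    def test_single_bin_reduces_to_totals(self, rng):
        p = rng.uniform(0.01, 0.5, size=500)
        y = rng.random(500) < p
        fit = binned_fit(p, y, n_bins=1)
        assert fit.expected.sum() == pytest.approx(p.sum())
        assert fit.observed.sum() == y.sum()

    def test_totals_conserved_across_bins(self, rng):
        p = rng.uniform(0.001, 0.9, size=2000)
        y = rng.random(2000) < p
        fit = binned_fit(p, y, n_bins=30)
        assert fit.expected.sum() == pytest.approx(p.sum())
        assert fit.observed.sum() == y.sum()

    def test_calibrated_simulation_has_high_overlap(self, rng):
        # labels drawn from the probabilities themselves: observed counts
        # track expected counts within binomial noise
        p = np.exp(rng.uniform(np.log(1e-3), np.log(0.3), size=50_000))
        y = rng.random(50_000) < p
        fit = binned_fit(p, y, n_bins=30)
        assert overlap(fit) > 0.85

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError):
            binned_fit([0.0, 0.5], [False, True], n_bins=2)


class TestHeldoutLoglik:
    def test_additivity_on_duplicated_pairs(self, truth3):
        ds = ts.simulate_dataset(truth3, n_pairs=1, length=120, seed=3)
        p = ds[0]
        import dataclasses
        p2 = dataclasses.replace(p, pair_id="copy")
        model = ts.build_model(ts.ModelConfig(family="kmer_table", k=3), seed=0)
        single = heldout_loglik(model, ts.PCPDataset([p]))
        double = heldout_loglik(model, ts.PCPDataset([p, p2]))
        assert double["total_loglik"] == pytest.approx(2 * single["total_loglik"])

    def test_empty_mask_scores_zero(self):
        pair = ts.ParentChildPair(pair_id="nn", parent=ts.NucSequence("NNNN"),
                                  child=ts.NucSequence("NNNN"), branch_length=0.1)
        model = ts.build_model(ts.ModelConfig(family="kmer_table", k=1), seed=0)
        out = heldout_loglik(model, ts.PCPDataset([pair]))
        assert out["total_loglik"] == 0.0

    def test_true_model_beats_misspecified_k1(self, truth5):
        # likelihood dominance: the generating model outscores a base-only
        # restriction on its own data
        ds = ts.simulate_dataset(truth5, n_pairs=150, length=300, seed=19)

        class TruthAdapter:
            def predict(self, parent):
                codes = parent.codes()
                lam = truth5.site_rates(codes)
                csp = np.full((len(codes), 4), 1 / 3)
                csp[np.arange(len(codes)), np.clip(codes, 0, 3)] = 0.0
                return lam, csp

        k1 = ts.build_model(ts.ModelConfig(family="kmer_table", k=1), seed=0)
        k1, _ = ts.train_model(k1, ds, ts.TrainingConfig(epochs=60, seed=0))
        truth_ll = heldout_loglik(TruthAdapter(), ds)["location_loglik"]
        k1_ll = heldout_loglik(k1, ds)["location_loglik"]
        assert truth_ll > k1_ll

    def test_true_model_auroc_beats_k1_in_majority_of_seeds(self, truth5):
        # over 10 simulation seeds, the generating model's AUROC should
        # exceed a trained base-composition (k=1) model's in the majority
        wins = 0
        for seed in range(10):
            ds = ts.simulate_dataset(truth5, n_pairs=40, length=200,
                                     seed=500 + seed)
            k1 = ts.build_model(ts.ModelConfig(family="kmer_table", k=1), seed=0)
            k1, _ = ts.train_model(k1, ds, ts.TrainingConfig(epochs=40, seed=0))

            def pooled_auroc(model):
                scores, labels = [], []
                for p in ds:
                    rates, _ = model.predict(p.parent)
                    pr = ts.site_mutation_prob(rates, p.branch_length)
                    scores.append(pr[p.site_mask])
                    labels.append(ts.mutation_indicators(p)[p.site_mask])
                return auroc(BinaryPredictionSet(np.concatenate(scores),
                                                 np.concatenate(labels)))

            class TruthAdapter:
                def predict(self, parent):
                    return truth5.site_rates(parent.codes()), None

            wins += pooled_auroc(TruthAdapter()) >= pooled_auroc(k1)
        assert wins >= 6
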