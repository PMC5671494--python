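import numpy as np
import pytest

from il17pred.dataio import EpitopeDataset
from il17pred.evaluate import (
    ConfusionCounts,
    confusion,
    kfold_cv,
    metrics,
    roc_auc,
    stratified_kfold,
    threshold_sweep,
)
from il17pred.models import SVMConfig, decision_scores, train_svm
from il17pred.synthdata import GeneratorConfig, generate_corpus, shuffle_labels


def naive_confusion(scores, labels, thr):
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        if s >= thr:
            tp, fp = tp + (y == 1), fp + (y == 0)
        else:
            fn, tn = fn + (y == 1), tn + (y == 0)
    return tp, fp, tn, fn


class TestConfusion:
    def test_basic(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0], 0.5)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_threshold_above_max(self):
        c = confusion([0.2, 0.8], [1, 0], 5.0)
        assert c.TP == 0 and c.FP == 0 and c.FN == 1 and c.TN == 1

    def test_matches_naive_loop_on_random_data(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        for thr in (-1.0, 0.0, 0.3):
            c = confusion(scores, labels, thr)
            assert (c.TP, c.FP, c.TN, c.FN) == naive_confusion(scores, labels, thr)
            assert c.total == 50

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1.0], [1, 0], 0.5)


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=50, FP=0, TN=50, FN=0))
        assert (m.ACC, m.SEN, m.SPC, m.MCC) == (100.0, 100.0, 100.0, 1.0)

    def test_chance_level(self):
        m = metrics(ConfusionCounts(TP=10, FN=10, TN=10, FP=10))
        assert m.ACC == 50.0 and m.MCC == 0.0

    def test_hand_computed_example(self):
        # TP=5, FN=3, TN=80, FP=12 evaluated by the four defining formulas
        tp, fn, tn, fp = 5, 3, 80, 12
        m = metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
        assert m.ACC == pytest.approx((tp + tn) / 100 * 100)
        assert m.SEN == pytest.approx(tp / (tp + fn) * 100)
        assert m.SPC == pytest.approx(tn / (tn + fp) * 100)
        mcc = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert m.MCC == pytest.approx(mcc)

    def test_zero_denominator_mcc_convention(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=5))
        assert m.MCC == 0.0

    def test_undefined_class_rates_flagged(self):
        m = metrics(ConfusionCounts(TP=0, FP=3, TN=7, FN=0))
        assert m.SEN is None and m.SPC is not None

    def test_agrees_with_naive_loop_randomized(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            scores = rng.normal(size=20)
            labels = rng.integers(0, 2, 20)
            if labels.sum() in (0, 20):
                continue
            thr = rng.normal()
            tp, fp, tn, fn = naive_confusion(scores, labels, thr)
            m = metrics(confusion(scores, labels, thr))
            assert m.ACC == pytest.approx((tp + tn) / 20 * 100)


def pairwise_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, pts = roc_auc([3, 2, 1, 0], [1, 1, 0, 0])
        assert auc == 1.0
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]

    def test_all_ties(self):
        auc, _ = roc_auc([1, 1, 1, 1], [1, 0, 1, 0])
        assert auc == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        scores = np.round(rng.normal(size=30), 1)  # rounding forces ties
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 1, 0
        auc, pts = roc_auc(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(np.trapezoid(pts[:, 1], pts[:, 0]), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(scores * 3), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestThresholdSweep:
    def test_separable_reaches_mcc_one(self):
        sweep, best = threshold_sweep([3, 2, -1, -2], [1, 1, 0, 0])
        best_row = max(sweep, key=lambda m: m.MCC)
        assert best_row.MCC == 1.0
        # any cutoff in (-1, 2] separates perfectly; ties break upward
        assert -1 < best <= 2

    def test_best_matches_exhaustive_search(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        _, best = threshold_sweep(scores, labels)
        best_mcc = metrics(confusion(scores, labels, best)).MCC
        # exhaustive oracle over a dense grid spanning the score range
        grid = np.linspace(scores.min() - 1, scores.max() + 1, 5000)
        oracle = max(metrics(confusion(scores, labels, t)).MCC for t in grid)
        assert best_mcc == pytest.approx(oracle, abs=1e-12)

    def test_finer_grid_never_lowers_best_mcc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        coarse = np.linspace(-2, 2, 5)
        fine = np.linspace(-2, 2, 50)
        best = lambda g: max(
            m.MCC for m in threshold_sweep(scores, labels, g)[0]
        )
        assert best(fine) >= best(coarse)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([1, 0], [1, 0], [])


class TestStratifiedKfold:
    def test_partition_property(self, default_corpus):
        folds = stratified_kfold(default_corpus, 10, seed=0)
        all_test = [i for _, test in folds for i in test]
        n = default_corpus.n_pos + default_corpus.n_neg
        assert sorted(all_test) == list(range(n))
        pos_sizes = [
            sum(1 for i in test if i < default_corpus.n_pos) for _, test in folds
        ]
        assert max(pos_sizes) - min(pos_sizes) <= 1

    def test_class_smaller_than_k(self, small_corpus):
        with pytest.raises(ValueError):
            stratified_kfold(small_corpus, small_corpus.n_pos + 1, seed=0)


class TestKfoldCV:
    def test_every_peptide_scored_once_and_deterministic(self, small_corpus):
        cfg = SVMConfig(kernel="linear")
        r1 = kfold_cv(small_corpus, "AAC", "SVM", cfg, k=5, seed=9)
        r2 = kfold_cv(small_corpus, "AAC", "SVM", cfg, k=5, seed=9)
        n = small_corpus.n_pos + small_corpus.n_neg
        assert sum(len(s) for s in r1.fold_scores) == n
        assert len(r1.pooled_scores) == n
        assert np.array_equal(r1.pooled_scores, r2.pooled_scores)
        assert r1.best_threshold == r2.best_threshold

    def test_label_shuffled_corpus_gives_null_auc(self):
        # permutation-null simulation: with labels shuffled, pooled AUC
        # should hover around 0.5
        base = generate_corpus(GeneratorConfig(n_pos=100, n_neg=250, seed=6))
        in_band = 0
        n_rep = 25
        for rep in range(n_rep):
            shuffled = shuffle_labels(base, seed=rep)
            r = kfold_cv(
                shuffled, "AAC", "SVM", SVMConfig(kernel="linear"), k=5, seed=rep
            )
            in_band += 0.4 <= r.auc <= 0.6
        assert in_band / n_rep >= 0.9

    def test_aap_foldwise_weights_differ_from_leaky_full_dataset_weights(
        self, small_corpus
    ):
        # the leak-free path retrains AAP weights inside each fold; training
        # them once on the full dataset (held-out fold included) produces
        # different pooled scores
        from sklearn.svm import SVC

        from il17pred.features import feature_matrix, train_aap_weights

        cfg = SVMConfig(kernel="linear")
        clean = kfold_cv(small_corpus, "AAP", "SVM", cfg, k=5, seed=3)

        leaky_weights = train_aap_weights(small_corpus)  # sees every fold
        peps = small_corpus.all_peptides()
        labels = np.array(small_corpus.labels())
        X = feature_matrix(peps, "AAP", leaky_weights)
        leaky_scores = np.empty(len(peps))
        for train_idx, test_idx in stratified_kfold(small_corpus, 5, seed=3):
            est = SVC(kernel="linear", C=1.0).fit(X[train_idx], labels[train_idx])
            leaky_scores[test_idx] = est.decision_function(X[test_idx])
        assert not np.allclose(clean.pooled_scores, leaky_scores)

    def test_pooled_metrics_reported_at_best_threshold(self, small_corpus):
        r = kfold_cv(small_corpus, "DPC", "SVM", SVMConfig(kernel="linear"), k=5, seed=0)
        recomputed = metrics(
            confusion(r.pooled_scores, r.pooled_labels, r.best_threshold)
        )
        assert r.pooled_metrics.MCC == recomputed.MCC
        assert r.pooled_metrics.AUC == r.auc
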