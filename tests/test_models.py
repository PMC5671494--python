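import numpy as np
import pytest

from il17pred.dataio import EpitopeDataset, Peptide
from il17pred.models import (
    ModelFormatError,
    RFConfig,
    SVMConfig,
    decision_scores,
    load_model,
    predict_labels,
    save_model,
    train_rf,
    train_svm,
)
from il17pred.synthdata import GeneratorConfig, generate_corpus


def _separable_ds():
    # L-rich positives vs P-rich negatives: trivially separable in AAC space
    pos = [Peptide(f"p{i}", "L" * 6 + aa) for i, aa in enumerate("ACDE")]
    neg = [Peptide(f"n{i}", "P" * 6 + aa) for i, aa in enumerate("ACDE")]
    return EpitopeDataset(pos, neg)


class TestSVMConfig:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            SVMConfig(kernel="sigmoid")
        with pytest.raises(ValueError):
            SVMConfig(c=0)
        with pytest.raises(ValueError):
            SVMConfig(kernel="rbf", g=0)
        with pytest.raises(ValueError):
            SVMConfig(j=-1)


class TestTrainSVM:
    @pytest.mark.parametrize("kernel", ["linear", "polynomial", "rbf"])
    def test_separable_training_scores_have_correct_sign(self, kernel):
        ds = _separable_ds()
        cfg = SVMConfig(kernel=kernel, c=10.0, d=2, g=0.01)
        model = train_svm(ds, "AAC", cfg)
        s_pos = decision_scores(model, ds.positives)
        s_neg = decision_scores(model, ds.negatives)
        assert np.all(s_pos > 0)
        assert np.all(s_neg < 0)

    def test_cost_factor_monotone_training_sensitivity(self):
        # on a fixed imbalanced, overlapping corpus, raising the penalty on
        # positive-class errors never lowers training sensitivity
        ds = generate_corpus(
            GeneratorConfig(n_pos=20, n_neg=120, signal_strength=0.25, seed=11)
        )
        sens = []
        for j in (1.0, 5.0, 50.0):
            model = train_svm(ds, "AAC", SVMConfig(kernel="linear", c=1.0, j=j))
            s = decision_scores(model, ds.positives)
            sens.append(np.mean(s >= 0))
        assert sens[0] <= sens[1] <= sens[2]

    def test_duplicated_training_set_same_decision_function(self):
        # on a separable corpus the optimum has no slack, so duplicating
        # every training point leaves the decision function unchanged
        ds = _separable_ds()
        doubled = EpitopeDataset(
            ds.positives + [Peptide(p.id + "b", p.seq) for p in ds.positives],
            ds.negatives + [Peptide(n.id + "b", n.seq) for n in ds.negatives],
        )
        cfg = SVMConfig(kernel="linear", c=100.0)
        probe = ds.all_peptides()
        s1 = decision_scores(train_svm(ds, "AAC", cfg), probe)
        s2 = decision_scores(train_svm(doubled, "AAC", cfg), probe)
        assert np.allclose(s1, s2, atol=1e-6)

    def test_single_class_rejected(self):
        ds = _separable_ds()
        with pytest.raises(ValueError):
            train_svm(EpitopeDataset(ds.positives, []), "AAC")

    def test_aap_model_carries_weights(self, small_corpus):
        model = train_svm(small_corpus, "AAP", SVMConfig(kernel="linear"))
        assert model.aap_weights is not None
        assert model.aap_weights.weights.shape == (400,)


class TestTrainRF:
    def test_separable_scores_near_extremes(self):
        ds = _separable_ds()
        model = train_rf(ds, "AAC", RFConfig(ntree=200, seed=0))
        # bootstrap resampling leaves a few trees without one toy class,
        # so training points score near, not exactly at, the extremes
        assert np.all(decision_scores(model, ds.positives) > 0.8)
        assert np.all(decision_scores(model, ds.negatives) < 0.2)

    def test_same_seed_identical_scores(self, small_corpus):
        probe = small_corpus.all_peptides()[:20]
        cfg = RFConfig(ntree=30, seed=7)
        s1 = decision_scores(train_rf(small_corpus, "DPC", cfg), probe)
        s2 = decision_scores(train_rf(small_corpus, "DPC", cfg), probe)
        assert np.array_equal(s1, s2)

    def test_score_equals_mean_of_tree_votes(self, small_corpus):
        model = train_rf(small_corpus, "DPC", RFConfig(ntree=25, seed=1))
        probe = small_corpus.all_peptides()[:15]
        scores, votes = decision_scores(model, probe, return_votes=True)
        assert votes.shape == (25, 15)
        assert np.allclose(scores, votes.mean(axis=0))
        assert np.all((scores >= 0) & (scores <= 1))

    def test_larger_ensemble_has_lower_score_variance(self):
        ds = generate_corpus(
            GeneratorConfig(n_pos=30, n_neg=80, signal_strength=0.5, seed=2)
        )
        probe = ds.all_peptides()[:10]

        def variance(ntree):
            scores = np.array(
                [
                    decision_scores(
                        train_rf(ds, "AAC", RFConfig(ntree=ntree, seed=s)), probe
                    )
                    for s in range(20)
                ]
            )
            return scores.var(axis=0).mean()

        assert variance(200) < variance(1)

    def test_mtry_exceeding_dimension_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            train_rf(small_corpus, "AAC", RFConfig(ntree=5, mtry=21))


class TestDecisionScores:
    def test_empty_input(self, dpc_model):
        assert decision_scores(dpc_model, []).shape == (0,)

    def test_purity_and_batching(self, dpc_model, small_corpus):
        peps = small_corpus.all_peptides()[:10]
        batch = decision_scores(dpc_model, peps)
        again = decision_scores(dpc_model, peps)
        singles = np.array([decision_scores(dpc_model, [p])[0] for p in peps])
        assert np.array_equal(batch, again)
        assert np.allclose(batch, singles)

    def test_too_short_peptide_rejected(self, dpc_model):
        with pytest.raises(ValueError, match="shorter"):
            decision_scores(dpc_model, [Peptide("p", "A")])


class TestPredictLabels:
    def test_threshold_classification(self, dpc_model, small_corpus):
        peps = small_corpus.all_peptides()[:20]
        scores = decision_scores(dpc_model, peps)
        rows = predict_labels(dpc_model, peps, threshold=0.5)
        for s, r in zip(scores, rows):
            assert r["label"] == ("inducer" if s >= 0.5 else "non-inducer")

    def test_negative_raw_svm_threshold(self, dpc_model, small_corpus):
        # operating thresholds may sit on the negative raw-score scale
        peps = small_corpus.all_peptides()
        scores = decision_scores(dpc_model, peps)
        i_hi = int(np.argmin(np.abs(scores - (-0.5))))
        i_lo = int(np.argmin(np.abs(scores - (-0.9))))
        rows = predict_labels(dpc_model, [peps[i_hi], peps[i_lo]], threshold=-0.6)
        if scores[i_hi] >= -0.6 > scores[i_lo]:
            assert [r["label"] for r in rows] == ["inducer", "non-inducer"]

    def test_raising_threshold_monotone(self, dpc_model, small_corpus):
        peps = small_corpus.all_peptides()[:50]
        low = {r["id"] for r in predict_labels(dpc_model, peps, threshold=0.0)
               if r["label"] == "inducer"}
        high = {r["id"] for r in predict_labels(dpc_model, peps, threshold=1.0)
                if r["label"] == "inducer"}
        assert high <= low

    def test_default_threshold_is_model_threshold(self, dpc_model, small_corpus):
        rows = predict_labels(dpc_model, small_corpus.positives[:3])
        assert all(r["threshold"] == dpc_model.threshold == 0.5 for r in rows)


class TestSerialization:
    def test_roundtrip_identical_scores(self, tmp_path, small_corpus):
        model = train_svm(small_corpus, "AAP", SVMConfig(kernel="polynomial", d=2))
        probe = generate_corpus(
            GeneratorConfig(n_pos=50, n_neg=50, seed=99)
        ).all_peptides()
        path = tmp_path / "model.bin"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(
            decision_scores(model, probe), decision_scores(back, probe)
        )
        assert back.feature_kind == "AAP"
        assert back.threshold == model.threshold

    def test_unknown_version_rejected(self, tmp_path, dpc_model):
        import joblib

        path = tmp_path / "model.bin"
        save_model(dpc_model, path)
        payload = joblib.load(path)
        payload["metadata"]["format_version"] = 999
        joblib.dump(payload, path)
        with pytest.raises(ModelFormatError, match="version"):
            load_model(path)

    def test_missing_aap_weights_rejected(self, tmp_path, small_corpus):
        import joblib

        model = train_svm(small_corpus, "AAP", SVMConfig(kernel="linear"))
        path = tmp_path / "model.bin"
        save_model(model, path)
        payload = joblib.load(path)
        payload["aap_weights"] = None
        joblib.dump(payload, path)
        with pytest.raises(ModelFormatError, match="weight"):
            load_model(path)

    def test_corrupted_file_rejected(self, tmp_path):
        path = tmp_path / "junk.bin"
        path.write_bytes(b"not a model")
        with pytest.raises(ModelFormatError):
            load_model(path)
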