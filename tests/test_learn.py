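"""Under-sampling, metrics, cross-validation and consensus prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simrepo.entities import AssociationSet
from simrepo.learn import (
    TrialConfig,
    cross_validate,
    evaluate,
    external_validate,
    predict_novel,
    sample_negatives,
    train,
)

from ._oracles import auc_pairwise


class TestTrialConfig:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(algorithm="perceptron")

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(n_folds=1)


class TestSampleNegatives:
    drugs = [f"D{i}" for i in range(6)]
    diseases = [f"X{i}" for i in range(6)]
    positives = AssociationSet({("D0", "X0"), ("D1", "X1"), ("D2", "X2")})

    def test_ratio_arithmetic(self):
        neg = sample_negatives(self.positives, self.drugs, self.diseases, ratio=2.0, seed=1)
        assert len(neg) == 6
        neg3 = sample_negatives(self.positives, self.drugs, self.diseases, ratio=3.0, seed=1)
        assert len(neg3) == 9

    def test_disjoint_from_positives(self):
        for seed in range(20):
            neg = sample_negatives(self.positives, self.drugs, self.diseases, seed=seed)
            assert not (neg.pairs & self.positives.pairs)

    def test_deterministic_and_seed_sensitive(self):
        a = sample_negatives(self.positives, self.drugs, self.diseases, seed=5)
        b = sample_negatives(self.positives, self.drugs, self.diseases, seed=5)
        c = sample_negatives(self.positives, self.drugs, self.diseases, seed=6)
        assert a.pairs == b.pairs
        assert a.pairs != c.pairs  # 33-candidate space; collision essentially impossible

    def test_insufficient_candidates_rejected(self):
        tiny = AssociationSet({("D0", "X0")})
        with pytest.raises(ValueError, match="candidate space"):
            sample_negatives(tiny, ["D0"], ["X0", "X1"], ratio=2.0, seed=0)


class TestEvaluate:
    def test_perfect_separation(self):
        rec = evaluate([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert rec.auc == 1.0 and rec.accuracy == 1.0
        assert rec.sensitivity == rec.specificity == rec.precision == 1.0

    def test_half_concordant(self):
        # concordant pairs: (0.9 vs 0.8), (0.9 vs 0.4); discordant: (0.3 vs both)
        rec = evaluate([0.9, 0.8, 0.4, 0.3], [1, 0, 0, 1])
        assert rec.auc == pytest.approx(0.5)

    def test_all_ties_gives_half(self):
        rec = evaluate([0.7, 0.7, 0.7, 0.7], [1, 1, 0, 0])
        assert rec.auc == pytest.approx(0.5)

    def test_single_class_auc_undefined(self):
        rec = evaluate([0.9, 0.2], [1, 1])
        assert rec.auc is None and rec.aupr is None

    def test_confusion_closed_forms(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        rec = evaluate(scores, labels, threshold=0.4)
        total = rec.tp + rec.tn + rec.fp + rec.fn
        assert total == 50
        assert rec.accuracy == pytest.approx((rec.tp + rec.tn) / total)
        assert rec.sensitivity == pytest.approx(rec.tp / (rec.tp + rec.fn))
        assert rec.specificity == pytest.approx(rec.tn / (rec.tn + rec.fp))
        assert rec.precision == pytest.approx(rec.tp / (rec.tp + rec.fp))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_auc_matches_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 201))
        # quantized scores force ties to exercise the 1/2 convention
        scores = np.round(rng.random(n), 1)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        rec = evaluate(scores, labels)
        assert rec.auc == pytest.approx(auc_pairwise(scores, labels), abs=1e-12)


class TestTrain:
    def test_separable_data_fits_perfectly(self):
        X = np.vstack([np.full((10, 12), 0.9), np.full((10, 12), 0.1)])
        X += np.random.default_rng(0).normal(0, 0.01, X.shape)
        y = np.array([1] * 10 + [0] * 10)
        clf = train(X, y, TrialConfig(algorithm="random-forest", seed=0))
        assert (clf.predict(X) == y).all()

    def test_constant_features_predict_class_prior(self):
        X = np.full((30, 12), 0.5)
        y = np.array([1] * 10 + [0] * 20)
        clf = train(X, y, TrialConfig(algorithm="logistic"))
        probs = clf.predict_proba(X)[:, 1]
        assert np.allclose(probs, 1 / 3, atol=0.02)

    def test_random_forest_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        X, y = rng.random((40, 12)), rng.integers(0, 2, 40)
        cfg = TrialConfig(algorithm="random-forest", n_estimators=50, seed=3)
        p1 = train(X, y, cfg).predict_proba(X)
        p2 = train(X, y, cfg).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train(np.random.rand(5, 12), np.ones(5), TrialConfig())

    @pytest.mark.parametrize("algo", ["svm-linear", "svm-rbf", "svm-quadratic", "svm-cubic"])
    def test_all_svm_variants_fit_and_score(self, algo):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0.8, 0.05, (15, 12)), rng.normal(0.2, 0.05, (15, 12))])
        y = np.array([1] * 15 + [0] * 15)
        clf = train(X, y, TrialConfig(algorithm=algo, seed=0))
        probs = clf.predict_proba(X)[:, 1]
        assert probs.shape == (30,) and (0 <= probs).all() and (probs <= 1).all()


@pytest.fixture(scope="module")
def fast_cfg():
    return TrialConfig(algorithm="random-forest", n_trials=1, n_folds=5,
                       n_estimators=100, seed=3)


class TestCrossValidate:
    def test_near_perfect_on_zero_noise_clusters(self, small_dataset, small_kernels, fast_cfg):
        report = cross_validate(small_dataset.gold, small_kernels, fast_cfg)
        assert report.mean("auc") >= 0.95

    def test_fold_bookkeeping(self, small_dataset, small_kernels):
        cfg = TrialConfig(algorithm="logistic", n_trials=1, n_folds=2, seed=0)
        report = cross_validate(small_dataset.gold, small_kernels, cfg)
        assert len(report.records) == 2
        assert set(report.records["fold"]) == {0, 1}

    def test_reproducible_for_fixed_master_seed(self, small_dataset, small_kernels, fast_cfg):
        r1 = cross_validate(small_dataset.gold, small_kernels, fast_cfg)
        r2 = cross_validate(small_dataset.gold, small_kernels, fast_cfg)
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_empty_gold_rejected(self, small_kernels, fast_cfg):
        with pytest.raises(ValueError, match="empty"):
            cross_validate(AssociationSet(set()), small_kernels, fast_cfg)

    def test_nonlinear_not_inferior_to_linear_under_noise(self, study_dataset, study_kernels):
        rf = cross_validate(
            study_dataset.gold, study_kernels,
            TrialConfig(algorithm="random-forest", n_trials=1, n_folds=5,
                        n_estimators=200, seed=0),
        )
        logit = cross_validate(
            study_dataset.gold, study_kernels,
            TrialConfig(algorithm="logistic", n_trials=1, n_folds=5, seed=0),
        )
        assert rf.mean("auc") >= logit.mean("auc") - 0.02


class TestExternalValidate:
    def test_held_out_recovered_on_zero_noise(self, small_dataset, small_kernels, fast_cfg):
        report = external_validate(small_dataset.held_out, small_dataset.gold,
                                   small_kernels, fast_cfg)
        assert report.mean("auc") >= 0.9

    def test_overlap_rejected(self, small_dataset, small_kernels, fast_cfg):
        leaky = AssociationSet(set(list(small_dataset.gold.pairs)[:2]))
        with pytest.raises(ValueError, match="overlap"):
            external_validate(leaky, small_dataset.gold, small_kernels, fast_cfg)

    def test_empty_test_set_rejected(self, small_dataset, small_kernels, fast_cfg):
        with pytest.raises(ValueError, match="empty"):
            external_validate(AssociationSet(set()), small_dataset.gold,
                              small_kernels, fast_cfg)


class TestPredictNovel:
    def test_consensus_rules(self, small_dataset, small_kernels):
        cfg = TrialConfig(algorithm="random-forest", n_trials=2, n_folds=5,
                          n_estimators=100, seed=4)
        gold_pair = small_dataset.gold.sorted_pairs()[0]
        held_pair = small_dataset.held_out.sorted_pairs()[0]
        # a cross-cluster pair: clusters differ between drug and disease
        cross = ("DR00_00", "DI01_00")
        assert cross not in small_dataset.gold
        records = predict_novel(
            small_dataset.gold, [gold_pair, held_pair, cross], small_kernels, cfg
        )
        by_pair = {r.pair: r for r in records}
        # gold pairs are never novel, whatever their score
        assert not by_pair[gold_pair].is_novel
        # a held-out within-cluster pair is recovered under zero noise
        assert by_pair[held_pair].is_novel
        assert by_pair[held_pair].support == cfg.n_trials
        # support below the trial count is never novel
        for r in records:
            if r.support < cfg.n_trials:
                assert not r.is_novel

    def test_sorted_by_mean_probability(self, small_dataset, small_kernels):
        cfg = TrialConfig(algorithm="logistic", n_trials=1, n_folds=5, seed=0)
        queries = [(d, s) for d in sorted(small_dataset.drugs)[:3]
                   for s in sorted(small_dataset.diseases)[:3]]
        records = predict_novel(small_dataset.gold, queries, small_kernels, cfg)
        probs = [r.mean_probability for r in records]
        assert probs == sorted(probs, reverse=True)
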