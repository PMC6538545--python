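"""Model construction and evaluation under repeated negative under-sampling.

The labelled problem is heavily imbalanced (every non-associated drug-disease
pair is a candidate negative), so training uses random under-sampling of
negatives at a fixed positive:negative ratio (default 1:2), repeated over
independent trials (default 30); each trial draws a fresh negative sample and
is evaluated by stratified 10-fold cross-validation.  Six classifiers are
supported: logistic regression, SVM with linear / RBF / quadratic / cubic
kernels, and random forest.

Novel indication candidates are non-gold pairs predicted positive by the
models of *all* trials (consensus rule), ranked by mean predicted
probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .entities import AssociationSet
from .features import build_feature_matrix, feature_array
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

ALGORITHMS = (
    "logistic",
    "svm-linear",
    "svm-rbf",
    "svm-quadratic",
    "svm-cubic",
    "random-forest",
)

METRIC_NAMES = ("accuracy", "auc", "aupr", "sensitivity", "specificity", "precision")


@dataclass
class TrialConfig:
    """Settings for one under-sampling/cross-validation experiment."""

    algorithm: str = "random-forest"
    negative_ratio: float = 2.0  # negatives per positive
    n_trials: int = 30
    n_folds: int = 10
    seed: int = 0
    decision_threshold: float = 0.5
    aggregator: str = "max"
    # hyperparameters (unremarkable defaults, all overridable)
    n_estimators: int = 500
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.negative_ratio <= 0:
            raise ValueError("negative_ratio must be positive")

    def trial_seed(self, trial: int) -> int:
        return self.seed + trial


@dataclass
class PredictionRecord:
    """Consensus prediction for one query pair across under-sampling trials."""

    pair: tuple[str, str]
    mean_probability: float
    support: int  # trials predicting positive at the decision threshold
    is_novel: bool


@dataclass
class EvaluationReport:
    """Per-(trial, fold) metric records with mean/sd aggregation."""

    records: pd.DataFrame  # columns: trial, fold, the six metrics, tp/fp/tn/fn
    config: TrialConfig | None = None

    def summary(self) -> pd.DataFrame:
        agg = self.records[list(METRIC_NAMES)].agg(["mean", "std"])
        return agg

    def mean(self, metric: str) -> float:
        return float(self.records[metric].mean())

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6f")


def make_classifier(config: TrialConfig, seed: int):
    """Instantiate the sklearn estimator for one trial."""
    if config.algorithm == "logistic":
        return LogisticRegression(max_iter=2000)
    if config.algorithm == "random-forest":
        return RandomForestClassifier(n_estimators=config.n_estimators, random_state=seed)
    kernel = {
        "svm-linear": ("linear", None),
        "svm-rbf": ("rbf", None),
        "svm-quadratic": ("poly", 2),
        "svm-cubic": ("poly", 3),
    }[config.algorithm]
    return SVC(
        kernel=kernel[0],
        degree=kernel[1] or 3,
        C=config.svm_c,
        gamma="scale",
        probability=True,
        random_state=seed,
    )


def train(features: np.ndarray, labels: np.ndarray, config: TrialConfig, seed: int | None = None):
    """Fit one classifier; returns the fitted estimator exposing predict_proba."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = make_classifier(config, config.seed if seed is None else seed)
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


def predict_proba(clf, features: np.ndarray) -> np.ndarray:
    """Positive-class probability scores."""
    return clf.predict_proba(np.asarray(features, dtype=float))[:, 1]


# ---------------------------------------------------------------------------
# negative sampling


def sample_negatives(
    positives: AssociationSet,
    drug_ids: Sequence[str],
    disease_ids: Sequence[str],
    ratio: float = 2.0,
    seed: int = 0,
    n: int | None = None,
    allow_fewer: bool = False,
) -> AssociationSet:
    """Uniform sample of non-associated pairs, ``ratio`` per positive.

    Drawn without replacement from (drugs x diseases) minus the positives;
    deterministic for a fixed seed.  ``n`` overrides the ratio-derived count.
    ``allow_fewer`` degrades to the full candidate set (with a warning) when
    the space is smaller than the request, instead of raising.
    """
    n_needed = round(ratio * len(positives)) if n is None else n
    candidates = [
        (d, s)
        for d in sorted(set(drug_ids))
        for s in sorted(set(disease_ids))
        if (d, s) not in positives
    ]
    if len(candidates) < n_needed:
        if not allow_fewer:
            raise ValueError(
                f"candidate space too small: need {n_needed} negatives, "
                f"only {len(candidates)} non-associated pairs available"
            )
        logger.warning(
            "negative candidate space smaller than requested (%d < %d); using all",
            len(candidates), n_needed,
        )
        n_needed = len(candidates)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_needed, replace=False)
    return AssociationSet({candidates[i] for i in idx}, label="negative")


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricRecord:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    auc: float | None
    aupr: float | None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "auc": self.auc, "aupr": self.aupr,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision,
        }


def evaluate(scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5) -> MetricRecord:
    """Threshold and ranking metrics for one scored set.

    AUC is the probability that a random positive outscores a random negative
    (ties count 1/2, the Mann-Whitney form); AUPR is the step-interpolated
    area under the precision-recall curve.  Both are None when only one class
    is present.  Precision is 0 when nothing is predicted positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))
    n = len(labels)
    accuracy = (tp + tn) / n if n else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    if pos.any() and (~pos).any():
        auc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    else:
        auc = aupr = None
    return MetricRecord(tp, fp, tn, fn, accuracy, sensitivity, specificity, precision, auc, aupr)


# ---------------------------------------------------------------------------
# cross-validation and external validation


def _labelled_features(
    positives: AssociationSet,
    negatives: AssociationSet,
    matrices: Mapping[str, SimilarityMatrix],
    known: AssociationSet,
    config: TrialConfig,
    leakage_mode: str,
) -> tuple[pd.DataFrame, np.ndarray]:
    pairs = positives.sorted_pairs() + negatives.sorted_pairs()
    df = build_feature_matrix(pairs, known, matrices, config.aggregator, leakage_mode)
    built = set(zip(df["drug_id"], df["disease_id"]))
    labels = np.array([1 if p in positives else 0 for p in pairs if p in built], dtype=int)
    return df, labels


def cross_validate(
    gold: AssociationSet,
    matrices: Mapping[str, SimilarityMatrix],
    config: TrialConfig,
    drug_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
    negative_exclude: AssociationSet | None = None,
) -> EvaluationReport:
    """Repeated under-sampling trials, each evaluated by stratified k-fold CV.

    Per trial: a fresh negative sample (trial-specific seed), features built
    with training leakage handling (a positive pair never sees its own gold
    entry), then stratified folds preserving the class ratio.  Folds missing
    a class are skipped with a warning.

    ``negative_exclude`` widens the set of pairs barred from negative
    sampling beyond the gold positives — e.g. the full ground-truth
    association set of a simulation, whose withheld positives would otherwise
    contaminate the negative labels.  The default (gold only) mirrors the
    real-data setting, where unknown true associations inevitably pollute the
    sampled negatives.
    """
    if not gold.pairs:
        raise ValueError("empty gold-standard set")
    drug_ids = list(drug_ids) if drug_ids is not None else matrices["drChe"].ids
    disease_ids = list(disease_ids) if disease_ids is not None else matrices["diPhe"].ids
    barred = AssociationSet(gold.pairs | (negative_exclude.pairs if negative_exclude else set()))
    rows = []
    for trial in range(config.n_trials):
        tseed = config.trial_seed(trial)
        negatives = sample_negatives(
            barred, drug_ids, disease_ids, seed=tseed,
            n=round(config.negative_ratio * len(gold)),
        )
        df, labels = _labelled_features(gold, negatives, matrices, gold, config, "train")
        X = feature_array(df)
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=tseed)
        for fold, (tr, te) in enumerate(skf.split(X, labels)):
            if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
                logger.warning("trial %d fold %d: single-class fold skipped", trial, fold)
                continue
            clf = train(X[tr], labels[tr], config, seed=tseed)
            rec = evaluate(predict_proba(clf, X[te]), labels[te], config.decision_threshold)
            rows.append({"trial": trial, "fold": fold, **rec.as_dict()})
    return EvaluationReport(records=pd.DataFrame(rows), config=config)


def external_validate(
    test_pairs: AssociationSet,
    gold: AssociationSet,
    matrices: Mapping[str, SimilarityMatrix],
    config: TrialConfig,
) -> EvaluationReport:
    """Evaluate models trained on the gold set against an external test set.

    Test positives must be disjoint from the gold positives.  Per trial a
    model is trained on the gold positives plus a fresh negative sample
    (training leakage handling), then scored on the test positives plus test
    negatives sampled from the test-drug x test-disease space minus all known
    positives; test features are built in predict mode against the full gold
    set.
    """
    if not test_pairs.pairs:
        raise ValueError("empty external test set")
    overlap = test_pairs.pairs & gold.pairs
    if overlap:
        raise ValueError(f"test pairs overlap the gold standard: {sorted(overlap)[:5]}")
    drug_ids = matrices["drChe"].ids
    disease_ids = matrices["diPhe"].ids
    test_drugs = sorted(test_pairs.drug_ids)
    test_diseases = sorted(test_pairs.disease_ids)
    known_all = AssociationSet(gold.pairs | test_pairs.pairs)
    rows = []
    for trial in range(config.n_trials):
        tseed = config.trial_seed(trial)
        train_neg = sample_negatives(gold, drug_ids, disease_ids, config.negative_ratio, tseed)
        df_tr, y_tr = _labelled_features(gold, train_neg, matrices, gold, config, "train")
        clf = train(feature_array(df_tr), y_tr, config, seed=tseed)

        test_neg = sample_negatives(
            known_all,
            test_drugs,
            test_diseases,
            seed=tseed + 1_000_003,
            n=round(config.negative_ratio * len(test_pairs)),
            allow_fewer=True,
        )
        df_te, y_te = _labelled_features(
            test_pairs, test_neg, matrices, gold, config, "predict"
        )
        rec = evaluate(predict_proba(clf, feature_array(df_te)), y_te, config.decision_threshold)
        rows.append({"trial": trial, "fold": 0, **rec.as_dict()})
    return EvaluationReport(records=pd.DataFrame(rows), config=config)


def predict_novel(
    gold: AssociationSet,
    query_pairs: Sequence[tuple[str, str]],
    matrices: Mapping[str, SimilarityMatrix],
    config: TrialConfig,
) -> list[PredictionRecord]:
    """Consensus extraction of candidate novel indications.

    Each of the ``n_trials`` models (gold positives + fresh negatives) scores
    every query pair; a pair is a novel candidate when predicted positive in
    all trials and absent from the gold set.  Output is sorted by mean
    probability, descending (pair id as deterministic tie-break).
    """
    drug_ids = matrices["drChe"].ids
    disease_ids = matrices["diPhe"].ids
    queries = list(dict.fromkeys(query_pairs))
    df_q = build_feature_matrix(queries, gold, matrices, config.aggregator, "predict")
    built = list(zip(df_q["drug_id"], df_q["disease_id"]))
    Xq = feature_array(df_q)
    probs = np.zeros((config.n_trials, len(built)))
    for trial in range(config.n_trials):
        tseed = config.trial_seed(trial)
        negatives = sample_negatives(gold, drug_ids, disease_ids, config.negative_ratio, tseed)
        df_tr, y_tr = _labelled_features(gold, negatives, matrices, gold, config, "train")
        clf = train(feature_array(df_tr), y_tr, config, seed=tseed)
        probs[trial] = predict_proba(clf, Xq)
    positive = probs >= config.decision_threshold
    records = []
    for j, pair in enumerate(built):
        support = int(positive[:, j].sum())
        records.append(
            PredictionRecord(
                pair=pair,
                mean_probability=float(probs[:, j].mean()),
                support=support,
                is_novel=(support == config.n_trials) and pair not in gold,
            )
        )
    records.sort(key=lambda r: (-r.mean_probability, r.pair))
    return records


def predictions_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug_id": [r.pair[0] for r in records],
            "disease_id": [r.pair[1] for r in records],
            "mean_probability": [r.mean_probability for r in records],
            "support": [r.support for r in records],
            "is_novel": [r.is_novel for r in records],
        }
    )
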