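"""Pair-feature assembly, negative sampling, classifiers and metrics.

A candidate (lncRNA, protein) pair is represented by combining the two node
embeddings (concatenation by default; Hadamard product and average are
alternatives). Positives are the known interactions; negatives are sampled
uniformly from the non-interacting pairs at a configurable ratio (1:1 by
default). Classification quality is measured under stratified k-fold
cross-validation with the standard confusion-matrix suite

    ACC = (TP+TN)/(TP+TN+FP+FN)        PRE = TP/(TP+FP)
    REC = TP/(TP+FN)                   SPEC = TN/(FP+TN)
    F1 = 2*PRE*REC/(PRE+REC)
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus AUC, the area under the ROC curve (equivalently the Mann-Whitney
probability that a random positive outscores a random negative). A metric
whose denominator is zero is reported as 0 with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .io_formats import EmbeddingTable, InteractionList

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("SVM", "RF", "NB", "LR")
METRIC_NAMES = ("ACC", "PRE", "REC", "SPEC", "MCC", "F1", "AUC")


@dataclass
class PairDataset:
    """Rows of (lncRNA id, protein id, feature vector, binary label)."""

    pairs: list[tuple[str, str]]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.pairs) != len(set(self.pairs)):
            raise ValueError("duplicate (lncRNA, protein) pairs")
        if self.X.shape[0] != len(self.pairs) or self.y.shape[0] != len(self.pairs):
            raise ValueError("row count mismatch")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    per_fold: list[dict[str, float]] = field(default_factory=list)

    def mean(self) -> dict[str, float]:
        return {
            k: float(np.mean([f[k] for f in self.per_fold])) for k in METRIC_NAMES
        }

    def sd(self) -> dict[str, float]:
        return {
            k: float(np.std([f[k] for f in self.per_fold], ddof=1))
            for k in METRIC_NAMES
        }


def combine_features(u: np.ndarray, v: np.ndarray, how: str = "concat") -> np.ndarray:
    if how == "concat":
        return np.concatenate([u, v])
    if how == "hadamard":
        return u * v
    if how == "average":
        return (u + v) / 2.0
    raise ValueError(f"unknown feature combiner {how!r}")


def make_pairs(
    embeddings: EmbeddingTable,
    interactions: InteractionList,
    neg_ratio: float = 1.0,
    seed: int = 0,
    combiner: str = "concat",
    lncrna_ids: list[str] | None = None,
    protein_ids: list[str] | None = None,
) -> PairDataset:
    """Balanced (by default) labeled pair dataset: all known interactions
    as positives, ``neg_ratio`` times as many uniformly sampled
    non-interacting (L, P) pairs as negatives. Candidate id pools default
    to the ids seen in the interaction list."""
    l_ids = sorted(lncrna_ids if lncrna_ids is not None else interactions.lncrna_ids())
    p_ids = sorted(protein_ids if protein_ids is not None else interactions.protein_ids())
    for node in [*l_ids, *p_ids]:
        if node not in embeddings:
            raise KeyError(f"no embedding for id {node!r}")
    positives = sorted(interactions.pairs)
    n_neg = round(neg_ratio * len(positives))
    pool = [
        (l, p) for l in l_ids for p in p_ids if (l, p) not in interactions
    ]
    if len(pool) < n_neg:
        raise ValueError(
            f"negative pool ({len(pool)}) smaller than requested ({n_neg})"
        )
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(pool), size=n_neg, replace=False)
    negatives = [pool[i] for i in sorted(neg_idx)]
    pairs = positives + negatives
    X = np.array(
        [
            combine_features(embeddings.vector(l), embeddings.vector(p), combiner)
            for l, p in pairs
        ]
    )
    y = np.array([1] * len(positives) + [0] * len(negatives))
    return PairDataset(pairs, X, y)


def kfold_split(
    dataset: PairDataset, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions (train indices, test indices); each
    sample is tested exactly once."""
    if len(dataset) < k:
        raise ValueError(f"dataset size {len(dataset)} < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train, test) for train, test in skf.split(dataset.X, dataset.y)
    ]


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & (predictions == 1))),
        TN=int(np.sum((labels == 0) & (predictions == 0))),
        FP=int(np.sum((labels == 0) & (predictions == 1))),
        FN=int(np.sum((labels == 1) & (predictions == 0))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> dict[str, float]:
    """The confusion-matrix metric suite; AUC from continuous scores when
    provided (requires both classes present)."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    pre = _safe_div(tp, tp + fp, "PRE")
    rec = _safe_div(tp, tp + fn, "REC")
    out = {
        "ACC": _safe_div(tp + tn, counts.total, "ACC"),
        "PRE": pre,
        "REC": rec,
        "SPEC": _safe_div(tn, fp + tn, "SPEC"),
        "MCC": _safe_div(
            tp * tn - fp * fn,
            float(np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))),
            "MCC",
        ),
        "F1": _safe_div(2 * pre * rec, pre + rec, "F1"),
    }
    if scores is not None and labels is not None:
        labels = np.asarray(labels)
        if len(set(labels.tolist())) < 2:
            raise ValueError("AUC needs both classes present")
        out["AUC"] = float(roc_auc_score(labels, scores))
    return out


def _build_classifier(name: str, seed: int):
    if name == "SVM":
        # quadratic kernel: pair features are concatenated node embeddings,
        # and the interaction signal lives in source x target cross-products,
        # which a degree-2 polynomial kernel represents exactly
        return SVC(kernel="poly", degree=2, gamma="scale", coef0=1.0, C=1.0,
                   random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "NB":
        return GaussianNB()
    if name == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def cross_validate(
    dataset: PairDataset,
    classifier_name: str = "SVM",
    k: int = 5,
    seed: int = 0,
) -> MetricReport:
    """Stratified k-fold fit/score loop; per-fold metric suite plus the
    fold mean +- sd via :class:`MetricReport`. The seed controls both the
    fold assignment and any classifier randomness."""
    if len(set(dataset.y.tolist())) < 2:
        raise ValueError("dataset must contain both classes")
    report = MetricReport()
    for train_idx, test_idx in kfold_split(dataset, k=k, seed=seed):
        clf = _build_classifier(classifier_name, seed)
        clf.fit(dataset.X[train_idx], dataset.y[train_idx])
        if hasattr(clf, "predict_proba"):
            scores = clf.predict_proba(dataset.X[test_idx])[:, 1]
        else:
            scores = clf.decision_function(dataset.X[test_idx])
        preds = clf.predict(dataset.X[test_idx])
        fold = metrics(
            confusion(dataset.y[test_idx], preds),
            scores,
            dataset.y[test_idx],
        )
        report.per_fold.append(fold)
    return report


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) pairs of the ROC curve, for export/plotting."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])
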