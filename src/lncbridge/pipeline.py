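"""Pair datasets, feature assembly, cross-validation and candidate ranking.

Labeled lncRNA-disease pairs never touch the bridge network: node attributes
and embeddings are computed once from the LDA-free network, so k-fold
cross-validation over pairs needs no per-fold recomputation and cannot leak
test edges into the representation.

Pair features concatenate the lncRNA block before the disease block, in one
of three modes: ``attribute`` (64 + 64), ``bridge`` (128 + 128) or ``both``
(192 + 192, attribute then bridge within each node block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .metrics import METRIC_COLUMNS, evaluate, pr_auc, roc_auc
from .network import BHNet, EntityId

logger = logging.getLogger(__name__)

MODES = ("attribute", "bridge", "both")
CLASSIFIERS = ("xgboost", "random_forest", "svm", "adaboost", "logistic_regression")

Pair = tuple[EntityId, EntityId]


@dataclass
class PairDataset:
    """Labeled lncRNA-disease pairs with a feature-mode tag."""

    pairs: list[Pair]
    labels: np.ndarray
    mode: str = "bridge"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels differ in length")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in dataset")
        pos = {p for p, y in zip(self.pairs, self.labels) if y == 1}
        neg = {p for p, y in zip(self.pairs, self.labels) if y == 0}
        if pos & neg:
            raise ValueError("a pair appears with both labels")
        logger.info("pair dataset: %d positive, %d negative (%s mode)",
                    len(pos), len(neg), self.mode)


def sample_negatives(
    positives: set[Pair],
    lncRNAs: set[EntityId],
    diseases: set[EntityId],
    ratio: float = 1.0,
    seed: int = 0,
) -> set[Pair]:
    """Uniform sample of unlabeled lncRNA-disease pairs, disjoint from the
    positives, of size round(ratio * |positives|).  Deterministic per seed."""
    n_needed = int(round(ratio * len(positives)))
    all_l = sorted(lncRNAs)
    all_d = sorted(diseases)
    candidates = [(l, d) for l in all_l for d in all_d if (l, d) not in positives]
    if len(candidates) < n_needed:
        raise ValueError(
            f"only {len(candidates)} unlabeled pairs available, need {n_needed}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_needed, replace=False)
    return {candidates[i] for i in idx}


def build_pair_dataset(
    positives: set[Pair],
    lncRNAs: set[EntityId],
    diseases: set[EntityId],
    *,
    mode: str = "bridge",
    ratio: float = 1.0,
    seed: int = 0,
) -> PairDataset:
    """Positives plus uniformly sampled negatives in deterministic order."""
    negatives = sample_negatives(positives, lncRNAs, diseases, ratio, seed)
    pairs = sorted(positives) + sorted(negatives)
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    return PairDataset(pairs, labels, mode)


def pair_features(
    pair: Pair, net: BHNet, attrs: np.ndarray | None, emb: np.ndarray | None, mode: str
) -> np.ndarray:
    """Feature vector of one pair: lncRNA block then disease block."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    blocks = []
    for node in pair:
        if node not in net.node_index:
            raise KeyError(f"node {node} not in network")
        i = net.node_index[node]
        if mode == "attribute":
            blocks.append(attrs[i])
        elif mode == "bridge":
            blocks.append(emb[i])
        else:
            blocks.append(np.concatenate([attrs[i], emb[i]]))
    return np.concatenate(blocks)


def feature_matrix(
    dataset: PairDataset, net: BHNet, attrs: np.ndarray | None, emb: np.ndarray | None
) -> np.ndarray:
    return np.vstack(
        [pair_features(p, net, attrs, emb, dataset.mode) for p in dataset.pairs])


def train_classifier(name: str, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit one of the five classifier types at library-default settings.

    Only the seed (and single-threading, for run-to-run reproducibility) is
    pinned.  Returns a fitted estimator with ``predict_proba``.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if name == "xgboost":
        clf = XGBClassifier(random_state=seed, n_jobs=1)
    elif name == "random_forest":
        clf = RandomForestClassifier(random_state=seed, n_jobs=1)
    elif name == "svm":
        clf = SVC(probability=True, random_state=seed)
    elif name == "adaboost":
        clf = AdaBoostClassifier(random_state=seed)
    elif name == "logistic_regression":
        clf = LogisticRegression(random_state=seed, max_iter=1000)
    else:
        raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")
    clf.fit(X, y)
    return clf


@dataclass
class CVResult:
    """Per-fold metric table plus fold-averaged and pooled summaries.

    ``pooled_auc``/``pooled_aupr`` concatenate all out-of-fold scores into a
    single ranking before computing the area, which is the alternative to
    averaging per-fold areas.
    """

    per_fold: pd.DataFrame
    mean: dict[str, float]
    pooled_auc: float
    pooled_aupr: float
    fold_indices: list[np.ndarray] = field(default_factory=list)

    def to_csv(self, path) -> None:
        df = self.per_fold.copy()
        mean_row = {"fold": "mean", **self.mean}
        pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True).to_csv(
            path, index=False, float_format="%.6f")


def make_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Stratified, shuffled k-fold test-index lists (disjoint, covering)."""
    labels = np.asarray(labels, dtype=int)
    minority = min(np.bincount(labels))
    if k < 2 or k > minority:
        raise ValueError(f"k={k} invalid for minority class of size {minority}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(
    dataset: PairDataset,
    net: BHNet,
    attrs: np.ndarray | None,
    emb: np.ndarray | None,
    classifier_name: str = "xgboost",
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of one classifier on pair features."""
    X = feature_matrix(dataset, net, attrs, emb)
    y = dataset.labels
    folds = make_folds(y, k, seed)
    rows = []
    pooled_scores = np.zeros(len(y))
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        clf = train_classifier(classifier_name, X[train_mask], y[train_mask], seed)
        scores = clf.predict_proba(X[test_idx])[:, 1]
        pooled_scores[test_idx] = scores
        rows.append({"fold": f, **evaluate(y[test_idx], scores)})
    df = pd.DataFrame(rows, columns=["fold"] + METRIC_COLUMNS)
    mean = {m: float(df[m].mean()) for m in METRIC_COLUMNS}
    return CVResult(
        per_fold=df,
        mean=mean,
        pooled_auc=roc_auc(y, pooled_scores),
        pooled_aupr=pr_auc(y, pooled_scores),
        fold_indices=folds,
    )


def rank_candidates(
    disease: EntityId,
    dataset: PairDataset,
    net: BHNet,
    attrs: np.ndarray | None,
    emb: np.ndarray | None,
    classifier_name: str = "xgboost",
    top_k: int = 10,
    seed: int = 0,
) -> list[tuple[EntityId, float]]:
    """Score every unlabeled lncRNA for one disease and return the top ``top_k``.

    The classifier is trained on all labeled pairs; candidates are the
    network's lncRNAs not already labeled with this disease.  Ties break by
    lncRNA name so the ranking is deterministic.
    """
    if disease not in net.node_index:
        raise KeyError(f"disease {disease} not in network")
    X = feature_matrix(dataset, net, attrs, emb)
    clf = train_classifier(classifier_name, X, dataset.labels, seed)

    labeled = {p[0] for p in dataset.pairs if p[1] == disease}
    candidates = sorted(
        e for e in net.nodes if e.node_type == "lncRNA" and e not in labeled)
    if not candidates:
        return []
    Xc = np.vstack(
        [pair_features((l, disease), net, attrs, emb, dataset.mode) for l in candidates])
    scores = clf.predict_proba(Xc)[:, 1]
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i].name))
    return [(candidates[i], float(scores[i])) for i in order[:top_k]]
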