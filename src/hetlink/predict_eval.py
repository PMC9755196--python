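"""Classifier training, k-fold cross-validation and candidate ranking.

The default classifier is gradient-boosted trees (LightGBM), with naive
Bayes, logistic regression, k-nearest-neighbour and AdaBoost baselines.
Threshold metrics (recall, precision, accuracy, F1) are computed at a
probability cut-off; AUC is the trapezoid area under the ROC curve and
AUPR the step-wise integral of the precision-recall curve, both with tied
scores grouped into a single operating point so the curves are exact,
interpolation-free functions of the ranking.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from hetlink.features import PairDataset, EmbeddingMatrix, pair_vector

logger = logging.getLogger(__name__)

__all__ = [
    "CVReport",
    "RankedCandidates",
    "CLASSIFIER_KINDS",
    "train_classifier",
    "score_rows",
    "compute_metrics",
    "kfold_cv",
    "evaluate_external",
    "rank_candidates",
]

METRIC_NAMES = ("recall", "precision", "accuracy", "f1", "auc", "aupr")

CLASSIFIER_KINDS = ("gbdt", "naive_bayes", "logistic", "knn", "adaboost")


@dataclass
class CVReport:
    per_fold: list[dict[str, float]]
    means: dict[str, float]
    roc_points: list[list[tuple[float, float]]]
    pr_points: list[list[tuple[float, float]]]
    config_hash: str

    def to_json(self, path=None) -> str:
        blob = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob

    def write_curves(self, roc_path, pr_path) -> None:
        """Per-fold curve coordinates as TSV: fold, x, y."""
        for path, folds, header in (
            (roc_path, self.roc_points, "fold\tfpr\ttpr\n"),
            (pr_path, self.pr_points, "fold\trecall\tprecision\n"),
        ):
            with open(path, "w") as fh:
                fh.write(header)
                for k, points in enumerate(folds):
                    for x, y in points:
                        fh.write(f"{k}\t{x:.8g}\t{y:.8g}\n")


@dataclass
class RankedCandidates:
    sm_id: str
    entries: list[tuple[str, float]]  # (mirna_id, probability), descending

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for rank, (m, p) in enumerate(self.entries, start=1):
                fh.write(f"{rank}\t{m}\t{p:.8g}\n")


def train_classifier(
    dataset: PairDataset,
    kind: str = "gbdt",
    params: dict | None = None,
    seed: int = 0,
):
    """Fit one of the five classifier kinds; returns the fitted estimator."""
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    y = np.asarray(dataset.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset contains a single class")
    params = dict(params or {})
    if kind == "gbdt":
        from lightgbm import LGBMClassifier

        defaults = dict(
            n_estimators=200, max_depth=6, learning_rate=0.1,
            random_state=seed, n_jobs=1, verbose=-1,
        )
        defaults.update(params)
        clf = LGBMClassifier(**defaults)
    elif kind == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB

        clf = GaussianNB(**params)
    elif kind == "logistic":
        from sklearn.linear_model import LogisticRegression

        defaults = dict(max_iter=2000)
        defaults.update(params)
        clf = LogisticRegression(**defaults)
    elif kind == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        defaults = dict(n_neighbors=5)
        defaults.update(params)
        clf = KNeighborsClassifier(**defaults)
    else:  # adaboost
        from sklearn.ensemble import AdaBoostClassifier

        defaults = dict(n_estimators=100, random_state=seed)
        defaults.update(params)
        clf = AdaBoostClassifier(**defaults)
    clf.fit(dataset.features, y)
    return clf


def score_rows(model, features: np.ndarray) -> np.ndarray:
    """Probability of the positive class for each feature row."""
    import warnings

    with warnings.catch_warnings():
        # sklearn warns about feature names when LightGBM round-trips ndarrays
        warnings.filterwarnings("ignore", message=".*feature names.*")
        proba = model.predict_proba(np.asarray(features, dtype=float))
    positive_col = list(model.classes_).index(1)
    return proba[:, positive_col]


# ---------------------------------------------------------------------------
# metrics


def _roc_pr_points(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Tie-grouped ROC (FPR, TPR) and PR (recall, precision) operating points."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    P = int(labels.sum())
    N = len(labels) - P
    # group boundaries where the score changes
    boundaries = np.flatnonzero(np.diff(s)) + 1
    cut = np.concatenate([boundaries, [len(s)]])
    tp_cum = np.cumsum(y)[cut - 1]
    group_sizes = cut
    fp_cum = group_sizes - tp_cum
    roc = [(0.0, 0.0)] + [
        (fp / N, tp / P) for fp, tp in zip(fp_cum, tp_cum)
    ]
    pr = [
        (tp / P, tp / (tp + fp) if tp + fp else 1.0)
        for tp, fp in zip(tp_cum, fp_cum)
    ]
    return roc, pr


def _auc_trapezoid(roc: list[tuple[float, float]]) -> float:
    area = 0.0
    for (x0, y0), (x1, y1) in zip(roc, roc[1:]):
        area += (x1 - x0) * 0.5 * (y0 + y1)
    return area


def _aupr_step(pr: list[tuple[float, float]]) -> float:
    area = 0.0
    prev_r = 0.0
    for r, p in pr:
        area += (r - prev_r) * p
        prev_r = r
    return area


def compute_metrics(
    labels, scores, threshold: float = 0.5
) -> dict[str, float]:
    """Six evaluation metrics from labels and predicted probabilities.

    Recall, precision, accuracy and F1 at the probability ``threshold``;
    AUC by trapezoid over the tie-grouped ROC curve and AUPR by step-wise
    integration of the precision-recall curve.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores disagree in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    accuracy = (tp + tn) / len(labels)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    roc, pr = _roc_pr_points(labels, scores)
    return {
        "recall": recall,
        "precision": precision,
        "accuracy": accuracy,
        "f1": f1,
        "auc": _auc_trapezoid(roc),
        "aupr": _aupr_step(pr),
    }


# ---------------------------------------------------------------------------
# cross-validation


def _fold_of_pairs(
    pairs: list[tuple[str, str]], labels: np.ndarray, k: int, seed: int
) -> np.ndarray:
    """Stratified fold assignment keyed on pair identity, not row order."""
    labels = np.asarray(labels)
    fold = np.empty(len(pairs), dtype=int)
    rng = np.random.default_rng(seed)
    for cls in (0, 1):
        rows = [i for i in range(len(pairs)) if labels[i] == cls]
        if len(rows) < k:
            raise ValueError(
                f"class {cls} has {len(rows)} pairs, fewer than k={k}"
            )
        # canonical order by pair id makes the assignment row-order invariant
        rows.sort(key=lambda i: pairs[i])
        perm = rng.permutation(len(rows))
        for slot, row_pos in enumerate(perm):
            fold[rows[row_pos]] = slot % k
    return fold


def kfold_cv(
    dataset: PairDataset,
    k: int = 10,
    kind: str = "gbdt",
    params: dict | None = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> CVReport:
    """Stratified pair-level k-fold cross-validation with the six metrics."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    fold = _fold_of_pairs(dataset.pairs, dataset.labels, k, seed)
    per_fold, rocs, prs = [], [], []
    for f in range(k):
        test = fold == f
        train_ds = PairDataset(
            pairs=[p for p, t in zip(dataset.pairs, test) if not t],
            features=dataset.features[~test],
            labels=dataset.labels[~test],
        )
        clf = train_classifier(train_ds, kind=kind, params=params, seed=seed)
        scores = score_rows(clf, dataset.features[test])
        y_test = dataset.labels[test]
        metrics = compute_metrics(y_test, scores, threshold)
        per_fold.append(metrics)
        roc, pr = _roc_pr_points(np.asarray(y_test), scores)
        rocs.append(roc)
        prs.append(pr)
    means = {
        name: float(np.mean([m[name] for m in per_fold])) for name in METRIC_NAMES
    }
    cfg = json.dumps(
        {"k": k, "kind": kind, "params": params or {}, "threshold": threshold, "seed": seed},
        sort_keys=True,
    )
    return CVReport(
        per_fold=per_fold,
        means=means,
        roc_points=rocs,
        pr_points=prs,
        config_hash=hashlib.sha256(cfg.encode()).hexdigest()[:16],
    )


def evaluate_external(
    model,
    embeddings: EmbeddingMatrix,
    pairs: list[tuple[str, str]],
    labels,
    pair_fn: str = "hadamard",
    threshold: float = 0.5,
) -> dict[str, float]:
    """Score an external hold-out pair set with a trained classifier.

    Pairs with an unembedded endpoint are skipped with a warning; if all
    are skipped this is an error.
    """
    if not pairs:
        raise ValueError("empty external pair list")
    labels = np.asarray(labels, dtype=int)
    kept_rows, kept_labels, skipped = [], [], []
    for (s, m), y in zip(pairs, labels):
        if s in embeddings and m in embeddings:
            kept_rows.append(pair_vector(embeddings.row(s), embeddings.row(m), pair_fn))
            kept_labels.append(y)
        else:
            skipped.append((s, m))
    if skipped:
        logger.warning("skipped %d pairs with unembedded endpoints: %s",
                       len(skipped), skipped[:5])
    if not kept_rows:
        raise ValueError("every external pair had an unembedded endpoint")
    scores = score_rows(model, np.stack(kept_rows))
    return compute_metrics(np.asarray(kept_labels), scores, threshold)


def rank_candidates(
    model,
    embeddings: EmbeddingMatrix,
    sm_id: str,
    known_positives: set[tuple[str, str]] | list[tuple[str, str]],
    pair_fn: str = "hadamard",
    top_n: int = 50,
    mirna_ids: list[str] | None = None,
) -> RankedCandidates:
    """Rank candidate miRNAs for one SM by descending predicted probability.

    Candidates are the embedded miRNAs (``mirna_ids`` filtered to those
    with embedding rows) minus the known positives of ``sm_id``; ties are
    broken by lexicographic miRNA id.
    """
    if sm_id not in embeddings:
        raise KeyError(f"unknown SM {sm_id!r}")
    if mirna_ids is None:
        raise ValueError("mirna_ids is required to identify candidate nodes")
    known = {m for s, m in known_positives if s == sm_id}
    candidates = sorted(m for m in mirna_ids if m in embeddings and m not in known)
    if not candidates:
        return RankedCandidates(sm_id=sm_id, entries=[])
    rows = np.stack(
        [pair_vector(embeddings.row(sm_id), embeddings.row(m), pair_fn) for m in candidates]
    )
    scores = score_rows(model, rows)
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i]))
    entries = [(candidates[i], float(scores[i])) for i in order[:top_n]]
    return RankedCandidates(sm_id=sm_id, entries=entries)
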