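"""Embedding merging, SM-miRNA pair vectors and balanced labelled datasets.

Two embedding matrices learned by independent algorithms are merged per
node -- by concatenation (the default, X = [U, V]), elementwise averaging
or elementwise product -- and an SM vector and a miRNA vector are combined
into one pair vector with one of four elementwise functions (Hadamard
product, average, difference, absolute difference).  Negatives are drawn
uniformly from the unobserved cells of the SM x miRNA grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingMatrix",
    "PairDataset",
    "merge_embeddings",
    "pair_vector",
    "build_dataset",
    "write_dataset",
    "read_dataset",
]

MERGE_METHODS = ("connection", "averaging", "multiplication")
PAIR_FUNCTIONS = ("hadamard", "average", "minus", "abs_minus")


@dataclass
class EmbeddingMatrix:
    ids: list[str]
    vectors: np.ndarray
    source: str = "merged"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate ids in embedding matrix")
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("ids and vector rows disagree")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite embedding entries")
        self._index = {n: i for i, n in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def row(self, node: str) -> np.ndarray:
        return self.vectors[self._index[node]]


@dataclass
class PairDataset:
    pairs: list[tuple[str, str]]
    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.pairs) == self.features.shape[0] == self.labels.shape[0]):
            raise ValueError("pairs, features and labels disagree in length")
        pos = {p for p, y in zip(self.pairs, self.labels) if y == 1}
        neg = {p for p, y in zip(self.pairs, self.labels) if y == 0}
        if pos & neg:
            raise ValueError("positive and negative pair sets overlap")


def merge_embeddings(
    u: EmbeddingMatrix, v: EmbeddingMatrix, method: str = "connection"
) -> EmbeddingMatrix:
    """Merge two per-node embedding matrices over an identical id set.

    ``connection`` concatenates rows (output dim = d_u + d_v); ``averaging``
    and ``multiplication`` act elementwise and require equal dims.  Output
    rows follow u's id order.
    """
    if method not in MERGE_METHODS:
        raise ValueError(f"unknown merge method {method!r}")
    if set(u.ids) != set(v.ids):
        diff = sorted(set(u.ids) ^ set(v.ids))
        raise ValueError(f"embedding id sets differ: {diff[:10]}")
    v_aligned = np.stack([v.row(n) for n in u.ids])
    if method == "connection":
        out = np.hstack([u.vectors, v_aligned])
    else:
        if u.dim != v.dim:
            raise ValueError(
                f"{method} requires equal dims, got {u.dim} and {v.dim}"
            )
        out = (
            0.5 * (u.vectors + v_aligned)
            if method == "averaging"
            else u.vectors * v_aligned
        )
    return EmbeddingMatrix(ids=list(u.ids), vectors=out, source="merged")


def pair_vector(
    sm_vec: np.ndarray, mi_vec: np.ndarray, function: str = "hadamard"
) -> np.ndarray:
    """Combine an SM vector and a miRNA vector into one pair vector."""
    sm_vec = np.asarray(sm_vec, dtype=float)
    mi_vec = np.asarray(mi_vec, dtype=float)
    if sm_vec.shape != mi_vec.shape:
        raise ValueError(f"length mismatch: {sm_vec.shape} vs {mi_vec.shape}")
    if function == "hadamard":
        return sm_vec * mi_vec
    if function == "average":
        return 0.5 * (sm_vec + mi_vec)
    if function == "minus":
        return sm_vec - mi_vec
    if function == "abs_minus":
        return np.abs(sm_vec - mi_vec)
    raise ValueError(f"unknown pair function {function!r}")


def build_dataset(
    positives: list[tuple[str, str]],
    all_sms: list[str],
    all_mirnas: list[str],
    embeddings: EmbeddingMatrix,
    pair_fn: str = "hadamard",
    ratio: float = 1.0,
    seed: int = 0,
) -> PairDataset:
    """Balanced labelled pair dataset with uniformly sampled negatives.

    Negatives are drawn uniformly without replacement from the SM x miRNA
    grid minus the positives, ``floor(ratio * len(positives))`` of them.
    Endpoints lacking an embedding row are excluded (with a warning for
    positives).  Deterministic under ``seed``.
    """
    sms = [s for s in all_sms if s in embeddings]
    mirnas = [m for m in all_mirnas if m in embeddings]
    dropped_entities = (len(all_sms) - len(sms)) + (len(all_mirnas) - len(mirnas))
    if dropped_entities:
        logger.warning("%d entities lack embedding rows and are excluded", dropped_entities)
    kept_pos = [
        (s, m) for s, m in positives if s in embeddings and m in embeddings
    ]
    if len(kept_pos) < len(positives):
        logger.warning(
            "%d positive pairs dropped for missing embeddings",
            len(positives) - len(kept_pos),
        )
    if not kept_pos:
        raise ValueError("no positive pair has embeddings for both endpoints")
    n_neg = int(np.floor(ratio * len(kept_pos)))
    sm_ix = {s: i for i, s in enumerate(sms)}
    mi_ix = {m: i for i, m in enumerate(mirnas)}
    pos_cells = np.unique(
        [sm_ix[s] * len(mirnas) + mi_ix[m] for s, m in kept_pos if s in sm_ix and m in mi_ix]
    )
    grid = len(sms) * len(mirnas)
    candidates = np.setdiff1d(np.arange(grid), pos_cells, assume_unique=True)
    if candidates.size < n_neg:
        raise ValueError(
            f"only {candidates.size} candidate negatives for {n_neg} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_neg, replace=False)
    negatives = [(sms[c // len(mirnas)], mirnas[c % len(mirnas)]) for c in sorted(chosen)]

    pairs = kept_pos + negatives
    labels = np.concatenate(
        [np.ones(len(kept_pos), dtype=int), np.zeros(len(negatives), dtype=int)]
    )
    features = np.stack(
        [pair_vector(embeddings.row(s), embeddings.row(m), pair_fn) for s, m in pairs]
    )
    return PairDataset(pairs=pairs, features=features, labels=labels)


def write_dataset(dataset: PairDataset, path) -> None:
    """Persist as TSV: sm_id, mirna_id, label, comma-joined features."""
    with open(path, "w") as fh:
        for (s, m), y, row in zip(dataset.pairs, dataset.labels, dataset.features):
            feats = ",".join(f"{v:.8g}" for v in row)
            fh.write(f"{s}\t{m}\t{y}\t{feats}\n")


def read_dataset(path) -> PairDataset:
    pairs, labels, rows = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            pairs.append((parts[0], parts[1]))
            labels.append(int(parts[2]))
            rows.append([float(v) for v in parts[3].split(",")])
    return PairDataset(pairs=pairs, features=np.asarray(rows), labels=np.asarray(labels))
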