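"""Relation-typed random-walk embedding (HIN2Vec-style).

Training data are <m, n, r, L> quadruples harvested from uniform random
walks on the heterogeneous graph: every ordered node pair within a window
of ``window_w`` hops is a positive whose relation id is the sequence of
edge types traversed between the two nodes; negatives corrupt the second
node with a random node of the same type.  A three-layer logistic network
scores P(r | m, n) = sigmoid( sum_k W_M[m]_k * W_N[n]_k * f01(W_R[r])_k )
with f01 the elementwise logistic squashing that keeps relation vectors in
[0, 1].  The per-sample log-likelihood

    log O = L * log P + (1 - L) * log(1 - P)

is maximised by stochastic gradient ascent with per-sample updates; the
node embedding output is the start-role matrix W_M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from hetlink.hetgraph import EDGE_TYPES, HeteroGraph

__all__ = [
    "Hin2VecConfig",
    "Hin2VecModel",
    "TrainingSample",
    "generate_walks",
    "extract_samples",
    "forward",
    "sample_gradients",
    "train",
]

_N_EDGE_TYPES = len(EDGE_TYPES)
_EDGE_TYPE_INDEX = {t: i for i, t in enumerate(EDGE_TYPES)}


@dataclass(frozen=True)
class Hin2VecConfig:
    dim: int = 32
    walks_per_node: int = 10
    walk_length: int = 80
    window_w: int = 2
    neg_per_pos: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    weighted_walks: bool = False  # weight-proportional neighbour choice
    tie_roles: bool = False  # share W_M and W_N
    seed: int = 0


@dataclass(frozen=True)
class TrainingSample:
    m: str
    n: str
    r: tuple[str, ...]
    label: int


@dataclass
class Hin2VecModel:
    """Weights of the three-layer logistic relation classifier."""

    node_ids: list[str]
    relation_labels: list[tuple[str, ...]]
    W_M: np.ndarray
    W_N: np.ndarray
    W_R: np.ndarray
    config: Hin2VecConfig

    _node_index: dict[str, int] = field(default_factory=dict, repr=False)
    _rel_index: dict[tuple[str, ...], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._node_index = {n: i for i, n in enumerate(self.node_ids)}
        self._rel_index = {r: i for i, r in enumerate(self.relation_labels)}

    def node_embeddings(self) -> tuple[list[str], np.ndarray]:
        """Final node vectors: the rows of the start-role matrix W_M."""
        return list(self.node_ids), self.W_M.copy()


# ---------------------------------------------------------------------------
# graph -> index space


class _IndexedGraph:
    """CSR view of a HeteroGraph for fast walking and typed lookups."""

    def __init__(self, graph: HeteroGraph):
        self.node_ids = graph.nodes()
        self.index = {n: i for i, n in enumerate(self.node_ids)}
        self.node_type = np.array(
            [("SM", "miRNA", "disease").index(graph.node_types[n]) for n in self.node_ids],
            dtype=np.int64,
        )
        indptr = [0]
        indices: list[int] = []
        for n in self.node_ids:
            nbrs = sorted(self.index[v] for v, _t, _w in graph.neighbors(n))
            indices.extend(nbrs)
            indptr.append(len(indices))
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.indices = np.asarray(indices, dtype=np.int64)
        self.degree = np.diff(self.indptr)
        # unordered type-pair -> edge-type id (unique in this schema)
        self._etype_of_pair = np.full((3, 3), -1, dtype=np.int64)
        for et, i in _EDGE_TYPE_INDEX.items():
            pair = {
                "sm-mi": (0, 1), "mi-dis": (1, 2), "sm-dis": (0, 2),
                "mi-mi": (1, 1), "sm-sm": (0, 0), "dis-dis": (2, 2),
            }[et]
            self._etype_of_pair[pair[0], pair[1]] = i
            self._etype_of_pair[pair[1], pair[0]] = i

    def edge_type_ids(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self._etype_of_pair[self.node_type[a], self.node_type[b]]


def _walk_matrix(
    ig: _IndexedGraph, walks_per_node: int, walk_length: int, rng: np.random.Generator
) -> np.ndarray:
    """All walks as an int matrix; rows from zero-degree starts repeat the start."""
    n = len(ig.node_ids)
    starts = np.tile(np.arange(n, dtype=np.int64), walks_per_node)
    walks = np.empty((starts.size, walk_length), dtype=np.int64)
    walks[:, 0] = starts
    cur = starts.copy()
    if ig.indices.size == 0:
        walks[:, 1:] = cur[:, None]
        return walks
    movable = ig.degree[cur] > 0
    safe = np.where(movable, cur, 0)
    for step in range(1, walk_length):
        draw = rng.random(cur.size)
        k = (draw * ig.degree[safe].clip(min=1)).astype(np.int64)
        nxt = ig.indices[ig.indptr[safe].clip(max=len(ig.indices) - 1) + k]
        cur = np.where(movable, nxt, cur)
        safe = np.where(movable, cur, 0)
        walks[:, step] = cur
    return walks


def generate_walks(
    graph: HeteroGraph, walks_per_node: int, walk_length: int, seed: int
) -> list[list[str]]:
    """Uniform random walks, ``walks_per_node`` per start node.

    Each step moves to a uniformly random neighbour regardless of node or
    edge type; a start node without neighbours yields a singleton walk.
    Deterministic under ``seed``.
    """
    if walk_length < 1:
        raise ValueError(f"walk_length must be >= 1, got {walk_length}")
    if graph.n_nodes() == 0:
        raise ValueError("empty graph")
    ig = _IndexedGraph(graph)
    rng = np.random.default_rng(seed)
    walks = _walk_matrix(ig, walks_per_node, walk_length, rng)
    out = []
    for row in walks:
        if ig.degree[row[0]] == 0:
            out.append([ig.node_ids[row[0]]])
        else:
            out.append([ig.node_ids[i] for i in row])
    return out


# ---------------------------------------------------------------------------
# relation coding: a typed path of length l <= w maps to one integer


def _relation_offset(length: int) -> int:
    off = 0
    for k in range(1, length):
        off += _N_EDGE_TYPES**k
    return off


def _decode_relation(code: int) -> tuple[str, ...]:
    length = 1
    while code >= _relation_offset(length + 1):
        length += 1
    rest = code - _relation_offset(length)
    types = []
    for _ in range(length):
        types.append(rest % _N_EDGE_TYPES)
        rest //= _N_EDGE_TYPES
    return tuple(EDGE_TYPES[t] for t in reversed(types))


def _pair_arrays(
    walks: np.ndarray, ig: _IndexedGraph, window_w: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positive (m, n, relation_code) arrays from all in-window ordered pairs."""
    ms, ns, codes = [], [], []
    L = walks.shape[1]
    # edge types along each walk
    et = ig.edge_type_ids(walks[:, :-1], walks[:, 1:]) if L > 1 else None
    for dist in range(1, min(window_w, L - 1) + 1):
        m = walks[:, : L - dist].ravel()
        n = walks[:, dist:].ravel()
        code = np.zeros(m.size, dtype=np.int64)
        for s in range(dist):
            code = code * _N_EDGE_TYPES + et[:, s : L - dist + s].ravel()
        code += _relation_offset(dist)
        ms.append(m)
        ns.append(n)
        codes.append(code)
    return np.concatenate(ms), np.concatenate(ns), np.concatenate(codes)


def _negative_samples(
    m: np.ndarray,
    n: np.ndarray,
    code: np.ndarray,
    ig: _IndexedGraph,
    neg_per_pos: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Corrupt the n endpoint type-preservingly, avoiding observed positives."""
    n_nodes = len(ig.node_ids)
    n_codes = int(code.max()) + 1 if code.size else 1
    pos_keys = np.unique((m * n_nodes + n) * n_codes + code)
    by_type = [np.flatnonzero(ig.node_type == t) for t in range(3)]
    mm = np.repeat(m, neg_per_pos)
    cc = np.repeat(code, neg_per_pos)
    target_type = ig.node_type[np.repeat(n, neg_per_pos)]
    nn = np.empty(mm.size, dtype=np.int64)
    pending = np.arange(mm.size)
    for _round in range(50):
        if pending.size == 0:
            break
        for t in range(3):
            sel = pending[target_type[pending] == t]
            if sel.size and by_type[t].size:
                nn[sel] = by_type[t][rng.integers(0, by_type[t].size, sel.size)]
            elif sel.size:
                nn[sel] = mm[sel]  # degenerate: no other node of that type
        keys = (mm[pending] * n_nodes + nn[pending]) * n_codes + cc[pending]
        clash = np.isin(keys, pos_keys, assume_unique=False)
        pending = pending[clash]
        # a type with <= 1 candidate can never escape the clash check
        if pending.size and all(
            by_type[t].size <= 1 for t in np.unique(target_type[pending])
        ):
            break
    return mm, nn, cc


def _sample_arrays(
    graph: HeteroGraph, config: Hin2VecConfig, rng: np.random.Generator
) -> tuple[_IndexedGraph, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ig = _IndexedGraph(graph)
    walks = _walk_matrix(ig, config.walks_per_node, config.walk_length, rng)
    # zero-degree starts produce stationary rows; drop them
    walks = walks[ig.degree[walks[:, 0]] > 0]
    if walks.shape[0] == 0 or walks.shape[1] < 2:
        raise ValueError("graph has no walkable edges")
    m, n, code = _pair_arrays(walks, ig, config.window_w)
    nm, nn, ncode = _negative_samples(m, n, code, ig, config.neg_per_pos, rng)
    all_m = np.concatenate([m, nm])
    all_n = np.concatenate([n, nn])
    all_code = np.concatenate([code, ncode])
    labels = np.concatenate(
        [np.ones(m.size, dtype=np.float64), np.zeros(nm.size, dtype=np.float64)]
    )
    return ig, all_m, all_n, all_code, labels


def extract_samples(
    walks: list[list[str]],
    graph: HeteroGraph,
    window_w: int,
    neg_per_pos: int,
    seed: int,
) -> list[TrainingSample]:
    """Materialise <m, n, r, L> training quadruples from walks.

    Every ordered pair within ``window_w`` hops of a walk yields a positive
    whose relation is the traversed edge-type sequence; each positive
    yields ``neg_per_pos`` type-preserving corruptions of n with label 0.
    """
    if window_w < 1:
        raise ValueError(f"window_w must be >= 1, got {window_w}")
    ig = _IndexedGraph(graph)
    rng = np.random.default_rng(seed)
    rows = [w for w in walks if len(w) >= 2]
    if not rows:
        return []
    lengths = {len(w) for w in rows}
    samples: list[TrainingSample] = []
    for L in sorted(lengths):
        mat = np.array(
            [[ig.index[v] for v in w] for w in rows if len(w) == L], dtype=np.int64
        )
        m, n, code = _pair_arrays(mat, ig, window_w)
        nm, nn, ncode = _negative_samples(m, n, code, ig, neg_per_pos, rng)
        for mi, ni, ci in zip(m, n, code):
            samples.append(
                TrainingSample(
                    ig.node_ids[mi], ig.node_ids[ni], _decode_relation(int(ci)), 1
                )
            )
        for mi, ni, ci in zip(nm, nn, ncode):
            samples.append(
                TrainingSample(
                    ig.node_ids[mi], ig.node_ids[ni], _decode_relation(int(ci)), 0
                )
            )
    return samples


# ---------------------------------------------------------------------------
# model mathematics


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def forward(model: Hin2VecModel, m: str, n: str, r: tuple[str, ...]) -> float:
    """P(r | m, n) = sigmoid( sum_k W_M[m]_k W_N[n]_k f01(W_R[r])_k )."""
    try:
        mi = model._node_index[m]
        ni = model._node_index[n]
        ri = model._rel_index[tuple(r)]
    except KeyError as exc:
        raise KeyError(f"unknown index {exc.args[0]!r}") from None
    q = _sigmoid(model.W_R[ri])
    return float(_sigmoid(np.sum(model.W_M[mi] * model.W_N[ni] * q)))


def sample_gradients(
    wm: np.ndarray, wn: np.ndarray, wr: np.ndarray, label: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the per-sample log-likelihood log O.

    Returns (d/dW_M[m], d/dW_N[n], d/dW_R[r]) for one sample, used by the
    ascent updates W := W + lr * grad.
    """
    q = _sigmoid(wr)
    p = _sigmoid(np.sum(wm * wn * q))
    err = label - p
    return err * wn * q, err * wm * q, err * wm * wn * q * (1.0 - q)


def sample_log_likelihood(
    wm: np.ndarray, wn: np.ndarray, wr: np.ndarray, label: float
) -> float:
    q = _sigmoid(wr)
    p = _sigmoid(np.sum(wm * wn * q))
    p = min(max(p, 1e-300), 1.0 - 1e-16)
    return float(label * np.log(p) + (1.0 - label) * np.log(1.0 - p))


@njit(cache=True)
def _sgd_epoch(
    W_M, W_N, W_R, m_idx, n_idx, r_idx, labels, order,
    lr0, step0, total_steps, tie_roles,
):  # pragma: no cover - exercised through train()
    d = W_M.shape[1]
    loss = 0.0
    for ii in range(order.shape[0]):
        k = order[ii]
        frac = (step0 + ii) / total_steps
        lr = lr0 * max(1.0 - frac, 1e-4)
        m = m_idx[k]
        n = n_idx[k]
        r = r_idx[k]
        L = labels[k]
        s = 0.0
        for j in range(d):
            q = 1.0 / (1.0 + np.exp(-W_R[r, j]))
            s += W_M[m, j] * W_N[n, j] * q
        p = 1.0 / (1.0 + np.exp(-s))
        if L > 0.5:
            loss -= np.log(max(p, 1e-300))
        else:
            loss -= np.log(max(1.0 - p, 1e-300))
        g = (L - p) * lr
        for j in range(d):
            q = 1.0 / (1.0 + np.exp(-W_R[r, j]))
            wm = W_M[m, j]
            wn = W_N[n, j]
            W_M[m, j] = wm + g * wn * q
            if tie_roles:
                W_M[n, j] = W_M[n, j] + g * wm * q
            else:
                W_N[n, j] = wn + g * wm * q
            W_R[r, j] = W_R[r, j] + g * wm * wn * q * (1.0 - q)
    return loss


def train(graph: HeteroGraph, config: Hin2VecConfig = Hin2VecConfig()) -> Hin2VecModel:
    """Train the relation classifier and return the fitted model.

    Stochastic gradient ascent on the per-sample log-likelihood with a
    linearly decaying learning rate; samples are reshuffled each epoch.
    Deterministic under ``config.seed``.  ``epochs=0`` returns the seeded
    random initialisation unchanged.
    """
    import logging

    logger = logging.getLogger(__name__)
    if graph.n_nodes() == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(config.seed)
    ig, m_idx, n_idx, code, labels = _sample_arrays(graph, config, rng)
    # compact relation vocabulary
    rel_codes = np.unique(code)
    rel_index = {int(c): i for i, c in enumerate(rel_codes)}
    r_idx = np.searchsorted(rel_codes, code)
    n_nodes = len(ig.node_ids)
    n_rels = rel_codes.size
    scale = 0.5 / config.dim
    W_M = rng.uniform(-scale, scale, (n_nodes, config.dim))
    W_N = W_M if config.tie_roles else rng.uniform(-scale, scale, (n_nodes, config.dim))
    W_R = rng.uniform(-scale, scale, (n_rels, config.dim))
    total = max(config.epochs * m_idx.size, 1)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(m_idx.size)
        loss = _sgd_epoch(
            W_M, W_N, W_R, m_idx, n_idx, r_idx, labels, order,
            config.learning_rate, step, total, config.tie_roles,
        )
        step += m_idx.size
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        logger.info("hin2vec epoch %d mean loss %.6f", epoch, loss / m_idx.size)
    if not (np.isfinite(W_M).all() and np.isfinite(W_N).all() and np.isfinite(W_R).all()):
        raise FloatingPointError("non-finite weights after training")
    return Hin2VecModel(
        node_ids=list(ig.node_ids),
        relation_labels=[_decode_relation(int(c)) for c in rel_codes],
        W_M=W_M,
        W_N=W_N,
        W_R=W_R,
        config=config,
    )
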