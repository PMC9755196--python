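"""Adversarial heterogeneous-network embedding (HeGAN-style).

A relation-aware discriminator scores a (node, neighbour-embedding,
relation) triple with a bilinear form, sigmoid(e_u^T M_r v), and is trained
to accept observed triples and reject (i) observed pairs under a wrong but
type-compatible relation and (ii) fake neighbour embeddings produced by a
generalised generator.  The generator maps its own node embedding through
a per-relation matrix plus Gaussian noise and a tanh nonlinearity, so its
fakes live in embedding space rather than being existing nodes, and is
trained to make the discriminator accept them.  The discriminator node
embeddings are the output.

In the three-node-type schema used here every unordered endpoint-type pair
corresponds to exactly one edge type, so the wrong-relation negative term
has no compatible candidates; for such relations the term falls back to
corrupting the neighbour node (type-preservingly) instead, which is what
gives the discriminator pair-level negatives -- without it, it would only
ever contrast real against generated samples and never learn which real
pairs actually stand in a relation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from hetlink.hetgraph import EDGE_ENDPOINTS, HeteroGraph

logger = logging.getLogger(__name__)

__all__ = [
    "HeGANConfig",
    "HeGANModel",
    "discriminator_score",
    "discriminator_loss",
    "disc_sample_gradients",
    "generator_sample",
    "train_hegan",
]


@dataclass(frozen=True)
class HeGANConfig:
    dim: int = 32
    epochs: int = 50
    disc_steps: int = 10  # discriminator minibatches per epoch
    gen_steps: int = 10
    lr_d: float = 0.01
    lr_g: float = 0.01
    noise_sigma: float = 0.1
    samples_per_edge: int = 1
    seed: int = 0


@dataclass
class HeGANModel:
    node_ids: list[str]
    disc_node_emb: np.ndarray
    disc_rel: dict[str, np.ndarray]
    gen_node_emb: np.ndarray
    gen_rel: dict[str, np.ndarray]
    config: HeGANConfig

    _node_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._node_index = {n: i for i, n in enumerate(self.node_ids)}

    def node_embeddings(self) -> tuple[list[str], np.ndarray]:
        """Final node vectors: the discriminator embedding matrix."""
        return list(self.node_ids), self.disc_node_emb.copy()


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def discriminator_score(
    model: HeGANModel, u: str, v_emb: np.ndarray, r: str
) -> float:
    """P(relation r holds between u and the embedded neighbour v)."""
    v_emb = np.asarray(v_emb, dtype=float)
    if v_emb.shape != (model.config.dim,):
        raise ValueError(
            f"neighbour embedding has shape {v_emb.shape}, expected ({model.config.dim},)"
        )
    if u not in model._node_index:
        raise KeyError(f"unknown node {u!r}")
    if r not in model.disc_rel:
        raise KeyError(f"unknown relation {r!r}")
    e_u = model.disc_node_emb[model._node_index[u]]
    return float(_sigmoid(e_u @ model.disc_rel[r] @ v_emb))


def disc_sample_gradients(
    e_u: np.ndarray, M_r: np.ndarray, v: np.ndarray, label: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the per-sample cross-entropy loss w.r.t. e_u and M_r.

    loss = -[y log s + (1-y) log(1-s)] with s = sigmoid(e_u^T M_r v).
    """
    s = _sigmoid(e_u @ M_r @ v)
    err = s - label
    return err * (M_r @ v), err * np.outer(e_u, v)


def disc_sample_loss(
    e_u: np.ndarray, M_r: np.ndarray, v: np.ndarray, label: float
) -> float:
    s = float(_sigmoid(e_u @ M_r @ v))
    s = min(max(s, 1e-300), 1.0 - 1e-16)
    return float(-(label * np.log(s) + (1.0 - label) * np.log(1.0 - s)))


def discriminator_loss(
    model: HeGANModel,
    u_ids: list[str],
    v_embs: np.ndarray,
    r_types: list[str],
    labels: np.ndarray,
) -> float:
    """Mean discriminator cross-entropy over a probe batch."""
    total = 0.0
    for u, v, r, y in zip(u_ids, v_embs, r_types, labels):
        e_u = model.disc_node_emb[model._node_index[u]]
        total += disc_sample_loss(e_u, model.disc_rel[r], v, float(y))
    return total / len(u_ids)


def generator_sample(
    model: HeGANModel, u: str, r: str, seed: int | None = None
) -> np.ndarray:
    """Fake neighbour embedding for (u, r): tanh(e_u^gen M_r^gen + noise)."""
    if u not in model._node_index:
        raise KeyError(f"unknown node {u!r}")
    e_u = model.gen_node_emb[model._node_index[u]]
    z = e_u @ model.gen_rel[r]
    if model.config.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        z = z + rng.normal(0.0, model.config.noise_sigma, z.shape)
    return np.tanh(z)


def _edge_arrays(graph: HeteroGraph, node_index: dict[str, int], rel_order: list[str]):
    """Directed (u, v, r) triples, one per orientation of every edge."""
    rel_index = {r: i for i, r in enumerate(rel_order)}
    u, v, r = [], [], []
    for a, b, et, _w in graph.edges:
        u.append(node_index[a]); v.append(node_index[b]); r.append(rel_index[et])
        u.append(node_index[b]); v.append(node_index[a]); r.append(rel_index[et])
    return (
        np.asarray(u, dtype=np.int64),
        np.asarray(v, dtype=np.int64),
        np.asarray(r, dtype=np.int64),
    )


def _wrong_relations(rel_order: list[str]) -> dict[int, list[int]]:
    """For each relation, the other relations with the same endpoint types."""
    out: dict[int, list[int]] = {}
    for i, ri in enumerate(rel_order):
        out[i] = [
            j
            for j, rj in enumerate(rel_order)
            if j != i and EDGE_ENDPOINTS[rj] == EDGE_ENDPOINTS[ri]
        ]
    return out


def train_hegan(graph: HeteroGraph, config: HeGANConfig = HeGANConfig()) -> HeGANModel:
    """Alternating adversarial training; returns the fitted model.

    Per epoch the discriminator takes ``disc_steps`` minibatch updates
    (real triples as true, wrong-relation and generated triples as false)
    and the generator ``gen_steps`` updates ascending log D on its fakes.
    Deterministic under ``config.seed``; ``epochs=0`` returns the seeded
    initialisation.
    """
    if graph.n_edges() == 0:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(config.seed)
    node_ids = graph.nodes()
    node_index = {n: i for i, n in enumerate(node_ids)}
    rel_order = sorted({et for _a, _b, et, _w in graph.edges})
    n, d = len(node_ids), config.dim

    scale = 1.0 / np.sqrt(d)
    disc_emb = rng.normal(0.0, scale, (n, d))
    gen_emb = rng.normal(0.0, scale, (n, d))
    disc_rel = {r: np.eye(d) + rng.normal(0.0, 0.01, (d, d)) for r in rel_order}
    gen_rel = {r: np.eye(d) + rng.normal(0.0, 0.01, (d, d)) for r in rel_order}

    eu, ev, er = _edge_arrays(graph, node_index, rel_order)
    wrong = _wrong_relations(rel_order)
    type_names = ("SM", "miRNA", "disease")
    v_type = np.array(
        [type_names.index(graph.node_types[nid]) for nid in node_ids], dtype=np.int64
    )
    same_type = {
        t: np.flatnonzero(v_type == t) for t in range(3)
    }
    n_dir = eu.size
    batch = max(1, (n_dir * config.samples_per_edge) // max(config.disc_steps, 1))

    def disc_batch_update(bu, bv, br, fake_v):
        """One minibatch step; returns mean loss over all terms."""
        grad_emb = np.zeros_like(disc_emb)
        grad_rel = {r: np.zeros((d, d)) for r in rel_order}
        total, count = 0.0, 0
        terms = [(bu, disc_emb[bv], br, 1.0)]
        # wrong-relation negatives where a type-compatible alternative
        # exists; otherwise corrupt the neighbour node instead
        wr = np.array([rng.choice(wrong[r]) if wrong[r] else -1 for r in br])
        keep = wr >= 0
        if keep.any():
            terms.append((bu[keep], disc_emb[bv[keep]], wr[keep], 0.0))
        corrupt = ~keep
        if corrupt.any():
            cv = np.array(
                [rng.choice(same_type[ty]) for ty in v_type[bv[corrupt]]]
            )
            terms.append((bu[corrupt], disc_emb[cv], br[corrupt], 0.0))
        terms.append((bu, fake_v, br, 0.0))
        for uu, vv, rr, y in terms:
            for ri in np.unique(rr):
                sel = rr == ri
                E = disc_emb[uu[sel]]
                V = vv[sel]
                M = disc_rel[rel_order[ri]]
                s = _sigmoid(np.sum((E @ M) * V, axis=1))
                s = np.clip(s, 1e-12, 1.0 - 1e-12)
                total += float(-(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)).sum())
                count += int(sel.sum())
                err = (s - y)[:, None]
                np.add.at(grad_emb, uu[sel], err * (V @ M.T))
                grad_rel[rel_order[ri]] += E.T @ (err * V)
        # node rows accumulate their per-sample SGD steps; the shared
        # relation matrices take the batch-mean step to stay stable
        disc_emb[...] -= config.lr_d * grad_emb
        for r in rel_order:
            disc_rel[r] -= config.lr_d * grad_rel[r] / max(count, 1)
        return total / max(count, 1)

    def gen_batch_update(bu, br):
        grad_emb = np.zeros_like(gen_emb)
        grad_rel = {r: np.zeros((d, d)) for r in rel_order}
        total, count = 0.0, 0
        for ri in np.unique(br):
            sel = br == ri
            r_name = rel_order[ri]
            Eg = gen_emb[bu[sel]]
            z = Eg @ gen_rel[r_name]
            if config.noise_sigma > 0:
                z = z + rng.normal(0.0, config.noise_sigma, z.shape)
            v_fake = np.tanh(z)
            Ed = disc_emb[bu[sel]]
            M = disc_rel[r_name]
            s = _sigmoid(np.sum((Ed @ M) * v_fake, axis=1))
            s = np.clip(s, 1e-12, 1.0 - 1e-12)
            total += float(-np.log(s).sum())
            count += int(sel.sum())
            grad_v = (s - 1.0)[:, None] * (Ed @ M)
            grad_z = grad_v * (1.0 - v_fake**2)
            np.add.at(grad_emb, bu[sel], grad_z @ gen_rel[r_name].T)
            grad_rel[r_name] += Eg.T @ grad_z
        gen_emb[...] -= config.lr_g * grad_emb
        for r in rel_order:
            gen_rel[r] -= config.lr_g * grad_rel[r] / max(count, 1)
        return total / max(count, 1)

    def sample_fakes(bu, br):
        Eg = gen_emb[bu]
        z = np.empty((bu.size, d))
        for ri in np.unique(br):
            sel = br == ri
            z[sel] = Eg[sel] @ gen_rel[rel_order[ri]]
        if config.noise_sigma > 0:
            z = z + rng.normal(0.0, config.noise_sigma, z.shape)
        return np.tanh(z)

    for epoch in range(config.epochs):
        d_loss = g_loss = 0.0
        for _ in range(config.disc_steps):
            pick = rng.integers(0, n_dir, batch)
            fakes = sample_fakes(eu[pick], er[pick])
            d_loss += disc_batch_update(eu[pick], ev[pick], er[pick], fakes)
        for _ in range(config.gen_steps):
            pick = rng.integers(0, n_dir, batch)
            g_loss += gen_batch_update(eu[pick], er[pick])
        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise FloatingPointError(f"non-finite adversarial loss at epoch {epoch}")
        logger.info(
            "hegan epoch %d disc loss %.6f gen loss %.6f",
            epoch, d_loss / max(config.disc_steps, 1), g_loss / max(config.gen_steps, 1),
        )
    if not (np.isfinite(disc_emb).all() and np.isfinite(gen_emb).all()):
        raise FloatingPointError("non-finite embeddings after training")
    return HeGANModel(
        node_ids=node_ids,
        disc_node_emb=disc_emb,
        disc_rel=disc_rel,
        gen_node_emb=gen_emb,
        gen_rel=gen_rel,
        config=config,
    )
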