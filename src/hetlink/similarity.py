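"""Disease semantic similarity from MeSH-style tree numbers, and similarity plumbing.

A disease located in the MeSH hierarchy by one or more dot-delimited tree
numbers induces a directed acyclic graph (DAG) over the disease and all of
its hierarchy ancestors.  Each ancestor ``t`` contributes semantically to
the disease ``d`` with weight ``delta**dist(t, d)`` where ``dist`` is the
shortest directed path length and ``delta`` (the semantic contribution
factor, conventionally 0.5) discounts each generation.  The similarity of
two diseases is the sum of both contributions over their shared DAG nodes,
normalised by the sum of their total semantic values:

    Sim(di, dj) = sum_{t in T_di ^ T_dj} (D_di(t) + D_dj(t)) / (DV(di) + DV(dj))

This module also integrates two miRNA similarity sources with an average
ensemble (mean where both define a pair, fallback to the one that does)
and converts dense similarity matrices into sparse weighted edge lists for
the heterogeneous graph.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DiseaseDAG",
    "SemanticParams",
    "SemanticProfile",
    "SimilarityMatrix",
    "build_disease_dags",
    "semantic_contribution",
    "disease_similarity",
    "disease_similarity_matrix",
    "integrate_mirna_similarity",
    "similarity_to_edges",
    "read_similarity_matrix",
    "write_similarity_matrix",
]


@dataclass
class DiseaseDAG:
    """One disease plus its ancestor DAG.

    ``nodes`` contains the disease itself and every ancestor implied by its
    tree numbers; ``edges`` are directed parent -> child pairs.  Ancestor
    positions that coincide with another named disease's full tree number
    are labelled with that disease's id; the rest stay anonymous (their
    node id is the raw tree-number prefix).
    """

    disease_id: str
    nodes: set[str]
    edges: set[tuple[str, str]]

    def children(self, node: str) -> list[str]:
        return [c for (p, c) in self.edges if p == node]


@dataclass(frozen=True)
class SemanticParams:
    """Semantic contribution factor delta in (0, 1); 0.5 by convention."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must lie in (0, 1), got {self.delta}")


@dataclass
class SemanticProfile:
    """Per-node semantic contributions D_d(t) and their sum DV(d)."""

    disease_id: str
    dv: float
    contributions: dict[str, float]
    delta: float = 0.5


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )

    def validate(self, atol: float = 1e-12) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("similarity matrix is not symmetric")
        if v.min() < -atol or v.max() > 1.0 + atol:
            raise ValueError("similarity values outside [0, 1]")

    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def value(self, a: str, b: str) -> float:
        ix = self.index()
        return float(self.values[ix[a], ix[b]])


def _prefixes(tree_number: str, *, row: object = None) -> list[str]:
    parts = tree_number.split(".")
    if any(p.strip() == "" for p in parts):
        where = f" (row {row!r})" if row is not None else ""
        raise ValueError(f"malformed tree number {tree_number!r}{where}")
    return [".".join(parts[: k + 1]) for k in range(len(parts))]


def build_disease_dags(
    tree_table: Iterable[tuple[str, str]],
) -> dict[str, DiseaseDAG]:
    """Build one ancestor DAG per disease from (disease_id, tree_number) rows.

    A disease with several tree numbers gets the union of their prefix
    chains.  Tree positions equal to the full tree number of a named
    disease are relabelled to that disease id, so that e.g. a parent
    disease appears under its own name inside its descendants' DAGs.
    """
    rows = list(tree_table)
    position_owner: dict[str, str] = {}
    by_disease: dict[str, list[str]] = {}
    for i, (disease_id, tree_number) in enumerate(rows):
        chain = _prefixes(str(tree_number), row=(i, disease_id))
        did = str(disease_id)
        by_disease.setdefault(did, []).append(tree_number)
        full = chain[-1]
        prev = position_owner.setdefault(full, did)
        if prev != did:
            raise ValueError(
                f"tree number {full!r} claimed by both {prev!r} and {did!r}"
            )

    def label(pos: str) -> str:
        return position_owner.get(pos, pos)

    dags: dict[str, DiseaseDAG] = {}
    for did, numbers in by_disease.items():
        nodes: set[str] = {did}
        edges: set[tuple[str, str]] = set()
        for tn in numbers:
            chain = _prefixes(tn)
            labelled = [label(p) for p in chain]
            labelled[-1] = did  # own position is the disease itself
            nodes.update(labelled)
            for parent, child in zip(labelled, labelled[1:]):
                if parent != child:
                    edges.add((parent, child))
        dags[did] = DiseaseDAG(disease_id=did, nodes=nodes, edges=edges)
    return dags


def _reverse_adjacency(dag: DiseaseDAG) -> dict[str, list[str]]:
    rev: dict[str, list[str]] = {n: [] for n in dag.nodes}
    for parent, child in dag.edges:
        rev[child].append(parent)
    return rev


def _assert_acyclic(dag: DiseaseDAG) -> None:
    # Kahn's algorithm; on failure report one edge on a cycle.
    indeg = {n: 0 for n in dag.nodes}
    for _, child in dag.edges:
        indeg[child] += 1
    queue = deque(n for n, d in indeg.items() if d == 0)
    seen = 0
    while queue:
        n = queue.popleft()
        seen += 1
        for p, c in dag.edges:
            if p == n:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
    if seen != len(dag.nodes):
        offending = next((p, c) for p, c in dag.edges if indeg[c] > 0)
        raise ValueError(f"cycle detected in DAG (edge {offending[0]} -> {offending[1]})")


def semantic_contribution(
    dag: DiseaseDAG, params: SemanticParams = SemanticParams()
) -> SemanticProfile:
    """Compute D_d(t) for every DAG node and the semantic value DV(d).

    D_d(d) = 1 and D_d(t) = max over children t' of delta * D_d(t'),
    equivalently delta ** (shortest directed path length from t to d):
    when several paths connect an ancestor to the disease the shortest one
    carries the largest contribution.
    """
    if dag.disease_id not in dag.nodes:
        raise ValueError(f"disease {dag.disease_id!r} missing from its own DAG")
    _assert_acyclic(dag)
    # BFS from d over reversed edges: distance = shortest path t -> ... -> d.
    rev = _reverse_adjacency(dag)
    dist = {dag.disease_id: 0}
    queue = deque([dag.disease_id])
    while queue:
        n = queue.popleft()
        for parent in rev[n]:
            if parent not in dist:
                dist[parent] = dist[n] + 1
                queue.append(parent)
    unreachable = dag.nodes - dist.keys()
    if unreachable:
        raise ValueError(
            f"nodes with no path to {dag.disease_id!r}: {sorted(unreachable)}"
        )
    contributions = {t: params.delta ** k for t, k in dist.items()}
    return SemanticProfile(
        disease_id=dag.disease_id,
        dv=float(sum(contributions.values())),
        contributions=contributions,
        delta=params.delta,
    )


def disease_similarity(profile_i: SemanticProfile, profile_j: SemanticProfile) -> float:
    """Shared-ancestor semantic similarity of two diseases in [0, 1]."""
    if profile_i.delta != profile_j.delta:
        raise ValueError(
            f"profiles computed with different delta "
            f"({profile_i.delta} vs {profile_j.delta})"
        )
    shared = profile_i.contributions.keys() & profile_j.contributions.keys()
    if not shared:
        return 0.0
    num = sum(
        profile_i.contributions[t] + profile_j.contributions[t] for t in shared
    )
    return float(num / (profile_i.dv + profile_j.dv))


def disease_similarity_matrix(
    dags: Mapping[str, DiseaseDAG], params: SemanticParams = SemanticParams()
) -> SimilarityMatrix:
    """All-pairs disease similarity over the named diseases in ``dags``."""
    if not dags:
        raise ValueError("empty DAG map")
    ids = sorted(dags)
    profiles = {d: semantic_contribution(dags[d], params) for d in ids}
    n = len(ids)
    values = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            s = disease_similarity(profiles[ids[a]], profiles[ids[b]])
            values[a, b] = values[b, a] = s
    return SimilarityMatrix(ids=ids, values=values)


def integrate_mirna_similarity(
    sim_a: SimilarityMatrix, sim_b: SimilarityMatrix
) -> SimilarityMatrix:
    """Average-ensemble integration of two miRNA similarity matrices.

    Pairs covered by both sources get the arithmetic mean; a pair covered
    by only one source keeps that source's value; pairs covered by neither
    (cross pairs of ids exclusive to different sources) get 0.  Output ids
    are the union, with unit diagonal.
    """
    for name, m in (("first", sim_a), ("second", sim_b)):
        diag = np.diag(m.values)
        if not np.allclose(diag, 1.0, atol=1e-9):
            raise ValueError(f"{name} matrix has non-unit diagonal entries")
    ids = sorted(set(sim_a.ids) | set(sim_b.ids))
    ix_a, ix_b = sim_a.index(), sim_b.index()
    n = len(ids)
    out = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j in range(i, n):
            b = ids[j]
            in_a = a in ix_a and b in ix_a
            in_b = a in ix_b and b in ix_b
            if in_a and in_b:
                v = 0.5 * (
                    sim_a.values[ix_a[a], ix_a[b]] + sim_b.values[ix_b[a], ix_b[b]]
                )
            elif in_a:
                v = sim_a.values[ix_a[a], ix_a[b]]
            elif in_b:
                v = sim_b.values[ix_b[a], ix_b[b]]
            else:
                v = 0.0
            out[i, j] = out[j, i] = v
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(ids=ids, values=out)


def similarity_to_edges(
    sim: SimilarityMatrix,
    *,
    threshold: float | None = 0.5,
    top_k: int | None = None,
) -> list[tuple[str, str, float]]:
    """Sparsify a similarity matrix into undirected weighted edges.

    Exactly one rule applies.  ``threshold`` keeps off-diagonal entries
    >= tau; ``top_k`` keeps, per node, its K most similar neighbours (the
    union over both endpoints, deduplicated).  Weight = similarity value;
    no self loops.
    """
    if (threshold is None) == (top_k is None):
        raise ValueError("specify exactly one of threshold or top_k")
    sim.validate()
    ids = sim.ids
    n = len(ids)
    edges: list[tuple[str, str, float]] = []
    if threshold is not None:
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
        for i in range(n):
            for j in range(i + 1, n):
                if sim.values[i, j] >= threshold:
                    edges.append((ids[i], ids[j], float(sim.values[i, j])))
        return edges
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    keep: set[tuple[int, int]] = set()
    for i in range(n):
        order = np.argsort(-sim.values[i])
        picked = 0
        for j in order:
            if j == i:
                continue
            keep.add((min(i, j), max(i, j)))
            picked += 1
            if picked >= top_k:
                break
    for i, j in sorted(keep):
        edges.append((ids[i], ids[j], float(sim.values[i, j])))
    return edges


def read_similarity_matrix(path) -> SimilarityMatrix:
    """Read a TSV similarity matrix with an id header row and id first column."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(r) for r in df.index] != ids:
        raise ValueError(f"{path}: row ids do not match column ids")
    return SimilarityMatrix(ids=ids, values=df.to_numpy(dtype=float))


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(
        path, sep="\t", float_format="%.8g"
    )
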