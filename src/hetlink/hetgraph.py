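"""Typed heterogeneous graph over small molecules, miRNAs and diseases.

Six undirected network slices feed the graph: three association networks
(sm-mi, mi-dis, sm-dis, unit weight) and three similarity networks
(sm-sm, mi-mi, dis-dis, weighted).  Every edge type joins a fixed pair of
node types, mature miRNA names are folded to their precursor, and
duplicate (pair, type) entries collapse to one edge.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NODE_TYPES = ("SM", "miRNA", "disease")

EDGE_TYPES = ("sm-mi", "mi-dis", "sm-dis", "mi-mi", "sm-sm", "dis-dis")

# unordered endpoint-type signature of each edge type
EDGE_ENDPOINTS: dict[str, frozenset[str]] = {
    "sm-mi": frozenset({"SM", "miRNA"}),
    "mi-dis": frozenset({"miRNA", "disease"}),
    "sm-dis": frozenset({"SM", "disease"}),
    "mi-mi": frozenset({"miRNA"}),
    "sm-sm": frozenset({"SM"}),
    "dis-dis": frozenset({"disease"}),
}

ASSOCIATION_TYPES = ("sm-mi", "mi-dis", "sm-dis")
SIMILARITY_TYPES = ("sm-sm", "mi-mi", "dis-dis")

_MATURE_ARM = re.compile(r"-(3p|5p)$")


def normalize_mirna_name(raw: str) -> str:
    """Fold a mature miRNA name to its precursor form.

    Lowercases (so ``miR`` becomes ``mir``) and strips a trailing mature-arm
    suffix ``-3p``/``-5p``; numeric paralog suffixes (``hsa-mir-125b-2``)
    are preserved.  Idempotent.
    """
    name = raw.strip().lower()
    if not name:
        raise ValueError("empty miRNA name")
    folded = _MATURE_ARM.sub("", name)
    if not folded:
        raise ValueError(f"miRNA name {raw!r} is a bare mature-arm suffix")
    return folded


def _normalize_disease_name(raw: str) -> str:
    return " ".join(raw.strip().split()).lower()


@dataclass
class HeteroGraph:
    """Undirected typed multigraph with at most one edge per (pair, type)."""

    node_types: dict[str, str] = field(default_factory=dict)
    edges: list[tuple[str, str, str, float]] = field(default_factory=list)
    adjacency: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)

    _edge_keys: set[tuple[str, str, str]] = field(default_factory=set, repr=False)

    def add_node(self, node_id: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        prev = self.node_types.setdefault(node_id, node_type)
        if prev != node_type:
            raise ValueError(
                f"node {node_id!r} declared both {prev!r} and {node_type!r}"
            )

    def add_edge(self, a: str, b: str, edge_type: str, weight: float = 1.0) -> bool:
        """Add one undirected edge; returns False if it was a duplicate."""
        if edge_type not in EDGE_ENDPOINTS:
            raise ValueError(f"unknown edge type {edge_type!r}")
        if a == b:
            raise ValueError(f"self-loop on {a!r} rejected")
        for n in (a, b):
            if n not in self.node_types:
                raise ValueError(f"edge endpoint {n!r} has no registered type")
        sig = frozenset({self.node_types[a], self.node_types[b]})
        if sig != EDGE_ENDPOINTS[edge_type]:
            raise ValueError(
                f"edge type {edge_type!r} incompatible with endpoint types "
                f"({self.node_types[a]}, {self.node_types[b]}) for ({a!r}, {b!r})"
            )
        lo, hi = (a, b) if a <= b else (b, a)
        key = (lo, hi, edge_type)
        if key in self._edge_keys:
            return False
        self._edge_keys.add(key)
        self.edges.append((lo, hi, edge_type, float(weight)))
        self.adjacency.setdefault(lo, []).append((hi, edge_type, float(weight)))
        self.adjacency.setdefault(hi, []).append((lo, edge_type, float(weight)))
        return True

    def neighbors(self, node: str) -> list[tuple[str, str, float]]:
        return self.adjacency.get(node, [])

    def nodes(self) -> list[str]:
        return sorted(self.node_types)

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self.node_types.items() if t == node_type)

    def n_nodes(self) -> int:
        return len(self.node_types)

    def n_edges(self) -> int:
        return len(self.edges)

    def drop_isolated(self) -> list[str]:
        isolated = [n for n in self.node_types if not self.adjacency.get(n)]
        for n in isolated:
            del self.node_types[n]
            self.adjacency.pop(n, None)
        if isolated:
            logger.warning("dropped %d isolated nodes", len(isolated))
        return isolated


def graph_slices(graph: HeteroGraph) -> dict[str, list[tuple[str, str, float]]]:
    """Per-edge-type slices with columns oriented by endpoint type.

    Cross-type edges are emitted with the first endpoint type of the slice
    (e.g. the miRNA) in the first column, so the slices round-trip through
    :func:`assemble_heterograph`.
    """
    out: dict[str, list[tuple[str, str, float]]] = {}
    for a, b, et, w in sorted(graph.edges):
        first = _node_type_of_endpoint(et, 0)
        if graph.node_types[a] != first:
            a, b = b, a
        out.setdefault(et, []).append((a, b, w))
    return out


def _node_type_of_endpoint(edge_type: str, which: int) -> str:
    pair = {
        "sm-mi": ("SM", "miRNA"),
        "mi-dis": ("miRNA", "disease"),
        "sm-dis": ("SM", "disease"),
        "mi-mi": ("miRNA", "miRNA"),
        "sm-sm": ("SM", "SM"),
        "dis-dis": ("disease", "disease"),
    }
    return pair[edge_type][which]


def assemble_heterograph(
    networks: Mapping[str, Sequence[tuple[str, str, float]]],
    mode: str = "HIN-3N",
) -> HeteroGraph:
    """Assemble the six network slices into one heterogeneous graph.

    ``networks`` maps edge-type labels to weighted edge lists; association
    slices normally carry weight 1 and similarity slices come pre-sparsified.
    ``HIN-3N`` uses all six slices and three node types; ``HIN-2N`` keeps
    only sm-mi, sm-sm and mi-mi (no disease nodes).  miRNA names are folded
    to precursor form, disease names case/whitespace-normalised, duplicates
    removed, and isolated nodes dropped.
    """
    if mode not in ("HIN-2N", "HIN-3N"):
        raise ValueError(f"mode must be HIN-2N or HIN-3N, got {mode!r}")
    keep = ("sm-mi", "sm-sm", "mi-mi") if mode == "HIN-2N" else EDGE_TYPES
    unknown = set(networks) - set(EDGE_TYPES)
    if unknown:
        raise ValueError(f"unknown network labels: {sorted(unknown)}")

    def canon(node: str, node_type: str) -> str:
        if node_type == "miRNA":
            return normalize_mirna_name(node)
        if node_type == "disease":
            return _normalize_disease_name(node)
        return node.strip()

    graph = HeteroGraph()
    for edge_type in keep:
        for a, b, w in networks.get(edge_type, []):
            ta = _node_type_of_endpoint(edge_type, 0)
            tb = _node_type_of_endpoint(edge_type, 1)
            ca, cb = canon(a, ta), canon(b, tb)
            if ca == cb:
                continue  # mature arms of one precursor, or a trivial self-pair
            graph.add_node(ca, ta)
            graph.add_node(cb, tb)
            graph.add_edge(ca, cb, edge_type, w)
    graph.drop_isolated()
    return graph


# ---------------------------------------------------------------------------
# TSV and embedding I/O


def read_edge_list(path, *, weighted: bool = True) -> list[tuple[str, str, float]]:
    """Read a TSV edge list ``id_a<TAB>id_b[<TAB>weight]``.

    Unweighted files get weight 1.0.  Ragged rows and non-numeric weights
    raise with the offending line number; an empty file is an empty list.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    expected = 3 if weighted else 2
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != expected:
                raise ValueError(
                    f"{path}:{lineno}: expected {expected} columns, got {len(parts)}"
                )
            if weighted:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
            else:
                w = 1.0
            edges.append((parts[0], parts[1], w))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str, float]], path) -> None:
    with open(path, "w") as fh:
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:.8g}\n")


def read_node_types(path) -> dict[str, str]:
    """Read the sidecar node-type TSV ``id<TAB>type``."""
    types: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if parts[1] not in NODE_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown node type {parts[1]!r}")
            types[parts[0]] = parts[1]
    return types


def write_node_types(types: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for node in sorted(types):
            fh.write(f"{node}\t{types[node]}\n")


def read_network_dir(directory) -> dict[str, list[tuple[str, str, float]]]:
    """Read the six-slice TSV directory written by :func:`write_network_dir`."""
    directory = Path(directory)
    networks = {}
    for edge_type in EDGE_TYPES:
        p = directory / f"{edge_type}.tsv"
        if p.exists():
            networks[edge_type] = read_edge_list(p, weighted=True)
    return networks


def write_network_dir(
    networks: Mapping[str, Sequence[tuple[str, str, float]]], directory
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for edge_type, edges in networks.items():
        write_edge_list(edges, directory / f"{edge_type}.tsv")


def write_embeddings(ids: Sequence[str], vectors: np.ndarray, path) -> None:
    """Write embeddings in word2vec text format (8 significant digits)."""
    vectors = np.asarray(vectors, dtype=float)
    if len(ids) != vectors.shape[0]:
        raise ValueError("ids and vector rows disagree")
    with open(path, "w") as fh:
        fh.write(f"{vectors.shape[0]} {vectors.shape[1]}\n")
        for node, row in zip(ids, vectors):
            fh.write(node + " " + " ".join(f"{v:.8g}" for v in row) + "\n")


def read_embeddings(path) -> tuple[list[str], np.ndarray]:
    """Read word2vec text format; returns (ids, matrix)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: malformed word2vec header")
        n, dim = int(header[0]), int(header[1])
        ids: list[str] = []
        rows = np.empty((n, dim))
        for k in range(n):
            parts = fh.readline().split(" ")
            if len(parts) < dim + 1:
                raise ValueError(f"{path}:{k + 2}: expected at least {dim + 1} fields")
            # node ids may contain spaces (disease names): the trailing dim
            # fields are the vector, everything before is the id
            ids.append(" ".join(parts[: len(parts) - dim]))
            rows[k] = [float(v) for v in parts[len(parts) - dim :]]
    return ids, rows
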