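"""End-to-end orchestration: networks -> graph -> embeddings -> CV.

The canonical flow mirrors the four-step design of the association
predictor: (1) assemble the heterogeneous information network from three
association and three similarity networks, (2) learn node embeddings with
the adversarial and the random-walk representation learners, (3) merge the
two embedding matrices per node, (4) form SM-miRNA pair vectors and train
a boosted-tree classifier under stratified k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from hetlink import hegan as hegan_mod
from hetlink import hin2vec as hin2vec_mod
from hetlink.features import EmbeddingMatrix, build_dataset, merge_embeddings
from hetlink.hetgraph import HeteroGraph, assemble_heterograph, normalize_mirna_name
from hetlink.predict_eval import CVReport, kfold_cv, train_classifier
from hetlink.similarity import (
    SimilarityMatrix,
    build_disease_dags,
    disease_similarity_matrix,
    similarity_to_edges,
)
from hetlink.synthgen import SyntheticData

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "six_networks",
    "build_graph",
    "compute_embedding",
    "combined_embedding",
    "pipeline_dataset",
    "run_cv_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "HIN-3N"
    embedders: tuple[str, ...] = ("hegan", "hin2vec")
    hegan_dim: int = 32
    hin2vec_dim: int = 32
    merge_method: str = "connection"
    pair_fn: str = "hadamard"
    classifier: str = "gbdt"
    classifier_params: dict | None = None
    k: int = 10
    threshold: float = 0.5
    sim_threshold: float = 0.5
    negative_ratio: float = 1.0
    seed: int = 0
    # representation-learner hyperparameters beyond the dimension
    hin2vec_overrides: dict = field(default_factory=dict)
    hegan_overrides: dict = field(default_factory=dict)


def stage_seed(master: int, stage: int) -> int:
    """Derive a per-stage seed below 2**31 from one master seed."""
    return int((master * 1_000_003 + stage * 7919 + 17) % (2**31 - 1))


def six_networks(
    associations: dict[str, list[tuple[str, str, float]]],
    sm_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    tree_table: list[tuple[str, str]],
    sim_threshold: float = 0.5,
) -> dict[str, list[tuple[str, str, float]]]:
    """Build all six network slices; disease similarity comes from the tree table."""
    dis_sim = disease_similarity_matrix(build_disease_dags(tree_table))
    return {
        "sm-mi": associations["sm-mi"],
        "mi-dis": associations["mi-dis"],
        "sm-dis": associations["sm-dis"],
        "sm-sm": similarity_to_edges(sm_sim, threshold=sim_threshold),
        "mi-mi": similarity_to_edges(mirna_sim, threshold=sim_threshold),
        "dis-dis": similarity_to_edges(dis_sim, threshold=sim_threshold),
    }


def build_graph(data: SyntheticData, config: PipelineConfig) -> HeteroGraph:
    networks = six_networks(
        data.associations,
        data.sm_sim,
        data.mirna_sim,
        data.tree_table,
        sim_threshold=config.sim_threshold,
    )
    return assemble_heterograph(networks, mode=config.mode)


def compute_embedding(
    graph: HeteroGraph, embedder: str, dim: int, seed: int, overrides: dict | None = None
) -> EmbeddingMatrix:
    overrides = dict(overrides or {})
    if embedder == "hin2vec":
        cfg = hin2vec_mod.Hin2VecConfig(dim=dim, seed=seed, **overrides)
        ids, vecs = hin2vec_mod.train(graph, cfg).node_embeddings()
        return EmbeddingMatrix(ids=ids, vectors=vecs, source="hin2vec")
    if embedder == "hegan":
        cfg = hegan_mod.HeGANConfig(dim=dim, seed=seed, **overrides)
        ids, vecs = hegan_mod.train_hegan(graph, cfg).node_embeddings()
        return EmbeddingMatrix(ids=ids, vectors=vecs, source="hegan")
    raise ValueError(f"unknown embedder {embedder!r}")


def combined_embedding(graph: HeteroGraph, config: PipelineConfig) -> EmbeddingMatrix:
    """Embeddings from the configured learners, merged when there are two."""
    embs = []
    for i, name in enumerate(config.embedders):
        dim = config.hegan_dim if name == "hegan" else config.hin2vec_dim
        overrides = (
            config.hegan_overrides if name == "hegan" else config.hin2vec_overrides
        )
        embs.append(
            compute_embedding(
                graph, name, dim, stage_seed(config.seed, 10 + i), overrides
            )
        )
    if len(embs) == 1:
        return embs[0]
    merged = embs[0]
    for other in embs[1:]:
        merged = merge_embeddings(merged, other, method=config.merge_method)
    return merged


def association_entities(
    data: SyntheticData, graph: HeteroGraph
) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Positive pairs and the SM/miRNA vocabularies with >= 1 association edge."""
    positives = [
        (s, normalize_mirna_name(m))
        for s, m in data.positives()
    ]
    positives = [
        (s, m) for s, m in positives
        if s in graph.node_types and m in graph.node_types
    ]
    sms = sorted({s for s, _m in positives})
    mirnas = sorted({m for _s, m in positives})
    return positives, sms, mirnas


def pipeline_dataset(data: SyntheticData, config: PipelineConfig):
    """Graph, merged embedding and balanced pair dataset for one run."""
    graph = build_graph(data, config)
    embedding = combined_embedding(graph, config)
    positives, sms, mirnas = association_entities(data, graph)
    dataset = build_dataset(
        positives,
        sms,
        mirnas,
        embedding,
        pair_fn=config.pair_fn,
        ratio=config.negative_ratio,
        seed=stage_seed(config.seed, 20),
    )
    return graph, embedding, dataset


def run_cv_pipeline(data: SyntheticData, config: PipelineConfig) -> CVReport:
    """Full pipeline ending in stratified k-fold cross-validation."""
    _graph, _embedding, dataset = pipeline_dataset(data, config)
    return kfold_cv(
        dataset,
        k=config.k,
        kind=config.classifier,
        params=config.classifier_params,
        threshold=config.threshold,
        seed=stage_seed(config.seed, 30),
    )


def _cv_for_embedding(
    data: SyntheticData,
    graph: HeteroGraph,
    embedding: EmbeddingMatrix,
    config: PipelineConfig,
) -> CVReport:
    positives, sms, mirnas = association_entities(data, graph)
    dataset = build_dataset(
        positives, sms, mirnas, embedding,
        pair_fn=config.pair_fn,
        ratio=config.negative_ratio,
        seed=stage_seed(config.seed, 20),
    )
    return kfold_cv(
        dataset,
        k=config.k,
        kind=config.classifier,
        params=config.classifier_params,
        threshold=config.threshold,
        seed=stage_seed(config.seed, 30),
    )


def ablation_reports(
    data: SyntheticData, config: PipelineConfig
) -> dict[str, CVReport]:
    """CV reports for each single learner and their merged features.

    Embeddings are trained once per learner and reused, so the merged run
    sees exactly the vectors the single-source runs were scored on.
    """
    graph = build_graph(data, config)
    singles: list[EmbeddingMatrix] = []
    reports: dict[str, CVReport] = {}
    for i, name in enumerate(config.embedders):
        dim = config.hegan_dim if name == "hegan" else config.hin2vec_dim
        overrides = (
            config.hegan_overrides if name == "hegan" else config.hin2vec_overrides
        )
        emb = compute_embedding(graph, name, dim, stage_seed(config.seed, 10 + i), overrides)
        singles.append(emb)
        reports[name] = _cv_for_embedding(data, graph, emb, config)
    if len(singles) > 1:
        merged = singles[0]
        for other in singles[1:]:
            merged = merge_embeddings(merged, other, method=config.merge_method)
        reports["merged"] = _cv_for_embedding(data, graph, merged, config)
    return reports
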