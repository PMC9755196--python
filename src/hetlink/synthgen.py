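"""Synthetic heterogeneous-network generator with planted low-rank structure.

Every entity (small molecule, miRNA, disease) gets a latent unit vector;
association edges are sampled with probability logistic(a * cos + b) in the
latent cosine, with the intercept b calibrated numerically so the mean
edge probability matches the target density.  Similarity matrices are the
clipped latent cosine plus Gaussian noise, and the disease tree table is
built by recursively bisecting disease latents into a depth-3 prefix tree,
so DAG-based semantic similarity correlates with latent similarity.  The
generator therefore plants exactly the statistical structure the
association predictor assumes: entities sharing latent factors are
co-associated and mutually similar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from hetlink.similarity import SimilarityMatrix

__all__ = ["SynthConfig", "SyntheticData", "generate", "write_dataset_dir", "read_dataset_dir"]

_COS_GAIN = 6.0  # slope of the logistic link on the latent cosine


@dataclass(frozen=True)
class SynthConfig:
    n_sm: int = 60
    n_mirna: int = 100
    n_disease: int = 40
    latent_dim: int = 4
    assoc_density: float = 0.05
    noise: float = 0.1
    holdout_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sm, self.n_mirna, self.n_disease, self.latent_dim) < 1:
            raise ValueError("entity counts and latent_dim must be positive")
        if not 0.0 < self.assoc_density < 1.0:
            raise ValueError("assoc_density must lie in (0, 1)")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        if not 0.0 <= self.holdout_frac < 1.0:
            raise ValueError("holdout_frac must lie in [0, 1)")
        if self.assoc_density * self.n_sm * self.n_mirna < 20:
            raise ValueError("expected SM-miRNA positives below 20; raise density or sizes")


@dataclass
class SyntheticData:
    config: SynthConfig
    sm_ids: list[str]
    mirna_ids: list[str]
    disease_ids: list[str]
    sm_latent: np.ndarray
    mirna_latent: np.ndarray
    disease_latent: np.ndarray
    associations: dict[str, list[tuple[str, str, float]]]
    sm_sim: SimilarityMatrix
    mirna_sim: SimilarityMatrix
    tree_table: list[tuple[str, str]]
    tree_position: dict[str, str]
    holdout_positive_pairs: list[tuple[str, str]]

    def positives(self) -> list[tuple[str, str]]:
        """Non-held-out SM-miRNA association pairs."""
        return [(a, b) for a, b, _w in self.associations["sm-mi"]]


def _unit_rows(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    x = rng.normal(size=(n, dim))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def _solve_intercept(cos: np.ndarray, density: float) -> float:
    """Bisection for b with mean(sigmoid(gain*cos + b)) == density."""
    lo, hi = -60.0, 60.0

    def mean_p(b: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(_COS_GAIN * cos + b)))))

    if not mean_p(lo) <= density <= mean_p(hi):
        raise ValueError(f"target density {density} unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_bipartite(
    rng: np.random.Generator,
    a_ids: list[str],
    b_ids: list[str],
    a_lat: np.ndarray,
    b_lat: np.ndarray,
    density: float,
) -> list[tuple[str, str, float]]:
    cos = a_lat @ b_lat.T
    b0 = _solve_intercept(cos, density)
    p = 1.0 / (1.0 + np.exp(-(_COS_GAIN * cos + b0)))
    draw = rng.random(p.shape)
    edges = []
    for i, j in zip(*np.nonzero(draw < p)):
        edges.append((a_ids[i], b_ids[j], 1.0))
    return edges


def _noisy_cosine_matrix(
    rng: np.random.Generator, ids: list[str], lat: np.ndarray, noise: float
) -> SimilarityMatrix:
    cos = np.clip(lat @ lat.T, 0.0, 1.0)
    if noise > 0:
        eps = rng.normal(0.0, noise, cos.shape)
        cos = cos + 0.5 * (eps + eps.T)  # symmetric noise
    cos = np.clip(cos, 0.0, 1.0)
    np.fill_diagonal(cos, 1.0)
    return SimilarityMatrix(ids=list(ids), values=cos)


def _bisect_tree(lat: np.ndarray, depth: int = 3) -> list[str]:
    """Recursive binary split on the axis of maximum variance.

    Returns one dot-delimited cluster path per row, e.g. ``C1.0.1``.
    Identical rows always land in the same leaf.
    """
    n = lat.shape[0]
    paths = [["C"] for _ in range(n)]
    groups: list[np.ndarray] = [np.arange(n)]
    for _level in range(depth):
        next_groups = []
        for rows in groups:
            sub = lat[rows]
            centred = sub - sub.mean(axis=0)
            cov = centred.T @ centred
            # principal axis; deterministic sign convention
            w, vecs = np.linalg.eigh(cov)
            axis = vecs[:, -1]
            if axis[np.argmax(np.abs(axis))] < 0:
                axis = -axis
            proj = centred @ axis
            med = np.median(proj)
            left = proj <= med + 1e-12
            if left.all() or (~left).all():
                # degenerate group (e.g. identical points): no split
                for i in rows:
                    paths[i].append("0")
                next_groups.append(rows)
                continue
            for i, is_left in zip(rows, left):
                paths[i].append("0" if is_left else "1")
            next_groups.append(rows[left])
            next_groups.append(rows[~left])
        groups = next_groups
    return [".".join(p) for p in paths]


def generate(config: SynthConfig = SynthConfig()) -> SyntheticData:
    """Generate the six input networks plus tree table and hold-out pairs.

    Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sm_ids = [f"DB{i:05d}" for i in range(1, config.n_sm + 1)]
    mirna_ids = [f"hsa-mir-{i:03d}" for i in range(1, config.n_mirna + 1)]
    disease_ids = [f"disease {i:03d}" for i in range(1, config.n_disease + 1)]

    sm_lat = _unit_rows(rng, config.n_sm, config.latent_dim)
    mi_lat = _unit_rows(rng, config.n_mirna, config.latent_dim)
    dis_lat = _unit_rows(rng, config.n_disease, config.latent_dim)

    sm_mi = _sample_bipartite(rng, sm_ids, mirna_ids, sm_lat, mi_lat, config.assoc_density)
    mi_dis = _sample_bipartite(rng, mirna_ids, disease_ids, mi_lat, dis_lat, config.assoc_density)
    sm_dis = _sample_bipartite(rng, sm_ids, disease_ids, sm_lat, dis_lat, config.assoc_density)

    sm_sim = _noisy_cosine_matrix(rng, sm_ids, sm_lat, config.noise)
    mi_sim = _noisy_cosine_matrix(rng, mirna_ids, mi_lat, config.noise)

    positions = _bisect_tree(dis_lat, depth=3)
    tree_position = dict(zip(disease_ids, positions))
    # unique leaf segment per disease keeps tree numbers unambiguous
    tree_table = [
        (d, f"{tree_position[d]}.{i + 1}") for i, d in enumerate(disease_ids)
    ]

    n_hold = int(np.floor(config.holdout_frac * len(sm_mi)))
    holdout: list[tuple[str, str]] = []
    if n_hold:
        pick = rng.choice(len(sm_mi), size=n_hold, replace=False)
        pick_set = set(pick.tolist())
        holdout = [(sm_mi[i][0], sm_mi[i][1]) for i in sorted(pick_set)]
        sm_mi = [e for i, e in enumerate(sm_mi) if i not in pick_set]

    return SyntheticData(
        config=config,
        sm_ids=sm_ids,
        mirna_ids=mirna_ids,
        disease_ids=disease_ids,
        sm_latent=sm_lat,
        mirna_latent=mi_lat,
        disease_latent=dis_lat,
        associations={"sm-mi": sm_mi, "mi-dis": mi_dis, "sm-dis": sm_dis},
        sm_sim=sm_sim,
        mirna_sim=mi_sim,
        tree_table=tree_table,
        tree_position=tree_position,
        holdout_positive_pairs=holdout,
    )


def write_dataset_dir(data: SyntheticData, directory) -> None:
    """Emit the TSV dialects consumed by the graph and similarity readers."""
    from hetlink.hetgraph import write_edge_list
    from hetlink.similarity import write_similarity_matrix

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for etype, edges in data.associations.items():
        write_edge_list(edges, directory / f"{etype}.tsv")
    write_similarity_matrix(data.sm_sim, directory / "sm_sim.tsv")
    write_similarity_matrix(data.mirna_sim, directory / "mirna_sim.tsv")
    with open(directory / "tree_table.tsv", "w") as fh:
        for d, tn in data.tree_table:
            fh.write(f"{d}\t{tn}\n")
    with open(directory / "holdout.tsv", "w") as fh:
        for s, m in data.holdout_positive_pairs:
            fh.write(f"{s}\t{m}\n")
    with open(directory / "manifest.json", "w") as fh:
        json.dump(asdict(data.config), fh, indent=2)


def read_dataset_dir(directory):
    """Read back the files written by :func:`write_dataset_dir`.

    Returns (associations, sm_sim, mirna_sim, tree_table, holdout, config_dict).
    """
    from hetlink.hetgraph import read_edge_list
    from hetlink.similarity import read_similarity_matrix

    directory = Path(directory)
    associations = {
        et: read_edge_list(directory / f"{et}.tsv")
        for et in ("sm-mi", "mi-dis", "sm-dis")
    }
    sm_sim = read_similarity_matrix(directory / "sm_sim.tsv")
    mirna_sim = read_similarity_matrix(directory / "mirna_sim.tsv")
    tree_table = []
    with open(directory / "tree_table.tsv") as fh:
        for line in fh:
            if line.strip():
                d, tn = line.rstrip("\n").split("\t")
                tree_table.append((d, tn))
    holdout = []
    hp = directory / "holdout.tsv"
    if hp.exists():
        with open(hp) as fh:
            for line in fh:
                if line.strip():
                    s, m = line.rstrip("\n").split("\t")
                    holdout.append((s, m))
    with open(directory / "manifest.json") as fh:
        config = json.load(fh)
    return associations, sm_sim, mirna_sim, tree_table, holdout, config
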