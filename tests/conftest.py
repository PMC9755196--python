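import numpy as np
import pytest

from hetlink.hetgraph import HeteroGraph
from hetlink.synthgen import SynthConfig, generate


def build_toy_graph() -> HeteroGraph:
    """Small deterministic three-type graph used across embedding tests."""
    g = HeteroGraph()
    sms = [f"sm{i}" for i in range(1, 5)]
    mis = [f"mi{i}" for i in range(1, 7)]
    dis = [f"d{i}" for i in range(1, 4)]
    for s in sms:
        g.add_node(s, "SM")
    for m in mis:
        g.add_node(m, "miRNA")
    for d in dis:
        g.add_node(d, "disease")
    sm_mi = [(1, 1), (1, 2), (2, 2), (2, 3), (3, 4), (3, 5), (4, 5), (4, 6), (1, 6)]
    for a, b in sm_mi:
        g.add_edge(f"sm{a}", f"mi{b}", "sm-mi")
    for a, b in [(1, 1), (2, 1), (3, 2), (4, 2), (5, 3), (6, 3)]:
        g.add_edge(f"mi{a}", f"d{b}", "mi-dis")
    for a, b in [(1, 1), (2, 2), (3, 3), (4, 3)]:
        g.add_edge(f"sm{a}", f"d{b}", "sm-dis")
    for a, b in [(1, 2), (3, 4), (5, 6)]:
        g.add_edge(f"mi{a}", f"mi{b}", "mi-mi", 0.8)
    for a, b in [(1, 2), (3, 4)]:
        g.add_edge(f"sm{a}", f"sm{b}", "sm-sm", 0.7)
    g.add_edge("d1", "d2", "dis-dis", 0.9)
    return g


@pytest.fixture(scope="session")
def toy_graph() -> HeteroGraph:
    return build_toy_graph()


@pytest.fixture(scope="session")
def synth_default():
    """The reference synthetic network (60 SMs, 100 miRNAs, 40 diseases)."""
    return generate(SynthConfig(seed=1))


def random_rooted_dag(rng: np.random.Generator, max_nodes: int = 15):
    """Random ancestor DAG rooted at node 'd0': every node reaches the sink."""
    from hetlink.similarity import DiseaseDAG

    n = int(rng.integers(1, max_nodes + 1))
    names = [f"d{i}" for i in range(n)]
    edges = set()
    for i in range(1, n):
        targets = rng.choice(i, size=int(rng.integers(1, min(i, 3) + 1)), replace=False)
        for j in targets:
            edges.add((names[i], names[j]))  # ancestor -> toward the disease
    return DiseaseDAG(disease_id=names[0], nodes=set(names), edges=edges)


def all_paths_contribution(dag, delta: float) -> dict[str, float]:
    """Brute-force oracle: max over all directed paths of delta**len."""
    children = {}
    for p, c in dag.edges:
        children.setdefault(p, []).append(c)

    def best(t):
        if t == dag.disease_id:
            return 1.0
        vals = []
        stack = [(t, 0)]
        # enumerate all paths by DFS (DAG: finite)
        def dfs(node, length):
            if node == dag.disease_id:
                vals.append(delta**length)
                return
            for c in children.get(node, []):
                dfs(c, length + 1)

        dfs(t, 0)
        return max(vals) if vals else None

    return {t: best(t) for t in dag.nodes}
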