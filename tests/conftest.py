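import random

import pytest

from scwib.graph_model import ScwibParams, SimilarityGraph


@pytest.fixture
def params():
    return ScwibParams(U=0.7, W=0.6, s=0.25)


def random_similarity_graph(seed: int, n: int, p_edge: float = 0.4) -> SimilarityGraph:
    """Random graph with weights spread over dropped/weak/strong bands."""
    rng = random.Random(seed)
    g = SimilarityGraph()
    verts = [f"v{i:02d}" for i in range(n)]
    for v in verts:
        g.add_vertex(v)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                band = rng.random()
                if band < 0.25:
                    w = rng.uniform(0.30, 0.60)
                elif band < 0.55:
                    w = rng.uniform(0.60, 0.70)
                else:
                    w = rng.uniform(0.70, 1.00)
                g.add_edge(verts[i], verts[j], min(w, 1.0))
    return g


def strong_path(n: int, weight: float = 0.8) -> SimilarityGraph:
    verts = [f"p{i:02d}" for i in range(n)]
    return SimilarityGraph.from_edges(
        [(a, b, weight) for a, b in zip(verts, verts[1:])], vertices=verts
    )


def strong_clique(n: int, weight: float = 0.9, prefix: str = "q") -> SimilarityGraph:
    verts = [f"{prefix}{i:02d}" for i in range(n)]
    edges = [
        (verts[i], verts[j], weight)
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return SimilarityGraph.from_edges(edges, vertices=verts)
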