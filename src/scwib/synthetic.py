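"""Seeded generator of fixture similarity graphs with known ground truth.

The generator plants a configurable set of clusters — each rejection-sampled
until it satisfies the two-level validity criterion under the generation
parameters — plus optional strong-edge chain segments (the adversarial case
for chaining control) and sparse background edges between groups.  Edge
weights are drawn so that the two thresholds are exercised independently:
strong edges uniform in [U, 1], weak edges uniform in [W, U), background
edges split between the sub-W band (which the reader would drop) and the
weak band.

Ground truth is returned alongside the graph so recovery can be scored;
the Rand index helper wraps scikit-learn's pair-counting implementation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

from sklearn.metrics import rand_score

from .graph_model import ScwibParams, SimilarityGraph, is_scwib, partition_edges

__all__ = ["PlantedModel", "GroundTruth", "generate", "partition_rand_index"]


@dataclass(frozen=True)
class PlantedModel:
    """Parameters of a planted-partition fixture.

    cluster_sizes
        sizes of the planted clusters (one cluster per entry).
    p_strong / p_weak
        within-cluster edge probabilities: each pair gets a strong edge
        with probability ``p_strong``; otherwise a weak edge with
        probability ``p_weak``.  With both at 1 every planted cluster is a
        strong clique.
    background_p
        probability of a spurious edge between vertices of different
        groups; its weight falls below U (half the time below W, where the
        reader drops it).
    chain_lengths
        lengths of planted strong-edge paths with no weak chords.
    params
        the (U, W, s) triple the fixture is built for; planted clusters
        are resampled until valid under these parameters.
    seed
        rng seed; generation is fully deterministic given the model.
    """

    cluster_sizes: Tuple[int, ...] = (4, 5, 6)
    p_strong: float = 1.0
    p_weak: float = 1.0
    background_p: float = 0.0
    chain_lengths: Tuple[int, ...] = ()
    params: ScwibParams = field(default_factory=ScwibParams)
    seed: int = 0
    max_attempts: int = 200

    def __post_init__(self) -> None:
        for p, name in (
            (self.p_strong, "p_strong"),
            (self.p_weak, "p_weak"),
            (self.background_p, "background_p"),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if any(n < 1 for n in self.cluster_sizes):
            raise ValueError("planted cluster sizes must be >= 1")
        if any(n < 2 for n in self.chain_lengths):
            raise ValueError("chain segments need at least 2 vertices")


@dataclass(frozen=True)
class GroundTruth:
    """Planted membership: clusters, chain segments, and all vertices."""

    clusters: Tuple[FrozenSet[str], ...]
    chains: Tuple[Tuple[str, ...], ...]

    def partition(self) -> List[FrozenSet[str]]:
        """Planted clusters; chain vertices count as singletons."""
        out = list(self.clusters)
        for chain in self.chains:
            out.extend(frozenset([v]) for v in chain)
        return out


def _sample_cluster_edges(
    members: Sequence[str], model: PlantedModel, rng: random.Random
) -> List[Tuple[str, str, float]]:
    U, W = model.params.U, model.params.W
    edges = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            r = rng.random()
            if r < model.p_strong:
                edges.append((members[i], members[j], rng.uniform(U, 1.0)))
            elif rng.random() < model.p_weak:
                w = rng.uniform(W, U)
                if w >= U:  # guard against closed upper end of uniform()
                    w = W
                edges.append((members[i], members[j], w))
    return edges


def generate(model: PlantedModel) -> Tuple[SimilarityGraph, GroundTruth]:
    """Build the fixture graph and its ground truth.

    Each planted cluster is rejection-sampled until it validates under the
    model's parameters; an infeasible setting (e.g. ``p_strong`` too low to
    ever connect the backbone at the requested size) raises ``ValueError``
    after ``max_attempts`` resamples.
    """
    rng = random.Random(model.seed)
    graph = SimilarityGraph()
    clusters: List[FrozenSet[str]] = []

    for ci, size in enumerate(model.cluster_sizes):
        members = [f"c{ci}_g{k}" for k in range(size)]
        for attempt in range(model.max_attempts):
            edges = _sample_cluster_edges(members, model, rng)
            trial = SimilarityGraph.from_edges(edges, vertices=members)
            part = partition_edges(trial, model.params)
            if is_scwib(members, part, model.params):
                break
        else:
            raise ValueError(
                f"could not realise a valid planted cluster of size {size} "
                f"in {model.max_attempts} attempts; parameters are infeasible"
            )
        for v in members:
            graph.add_vertex(v)
        for a, b, w in edges:
            graph.add_edge(a, b, w)
        clusters.append(frozenset(members))

    chains: List[Tuple[str, ...]] = []
    for hi, length in enumerate(model.chain_lengths):
        members = [f"h{hi}_g{k}" for k in range(length)]
        for v in members:
            graph.add_vertex(v)
        for a, b in zip(members, members[1:]):
            graph.add_edge(a, b, rng.uniform(model.params.U, 1.0))
        chains.append(tuple(members))

    if model.background_p > 0:
        groups: Dict[str, int] = {}
        for gi, grp in enumerate(list(clusters) + [frozenset(c) for c in chains]):
            for v in grp:
                groups[v] = gi
        verts = sorted(graph.vertices)
        W, U = model.params.W, model.params.U
        for i in range(len(verts)):
            for j in range(i + 1, len(verts)):
                a, b = verts[i], verts[j]
                if groups.get(a) == groups.get(b):
                    continue
                if rng.random() < model.background_p:
                    # half the noise sits below W (dropped at read time),
                    # half in the weak band; never strong.
                    if rng.random() < 0.5:
                        w = rng.uniform(0.3, W)
                        if w >= W:
                            w = 0.3
                    else:
                        w = rng.uniform(W, U)
                        if w >= U:
                            w = W
                    graph.add_edge(a, b, w)

    return graph, GroundTruth(clusters=tuple(clusters), chains=tuple(chains))


def partition_rand_index(
    truth: Iterable[Iterable[str]], predicted: Iterable[Iterable[str]]
) -> float:
    """Rand index between two partitions given as collections of sets.

    Vertices present in one partition but not the other are treated as
    singletons in the partition that lacks them.
    """
    t_sets = [set(c) for c in truth]
    p_sets = [set(c) for c in predicted]
    universe = sorted(set().union(*t_sets, *p_sets)) if (t_sets or p_sets) else []

    def labels(sets: List[Set[str]]) -> List[int]:
        lab: Dict[str, int] = {}
        for i, c in enumerate(sets):
            for v in c:
                if v in lab:
                    raise ValueError(f"vertex {v!r} appears in two clusters")
                lab[v] = i
        nxt = len(sets)
        out = []
        for v in universe:
            if v not in lab:
                lab[v] = nxt
                nxt += 1
            out.append(lab[v])
        return out

    if not universe:
        return 1.0
    return float(rand_score(labels(t_sets), labels(p_sets)))
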