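"""Greedy disjoint decomposition of a similarity graph into gene families.

Candidate clusters are re-enumerated on the current residual graph, the
largest is emitted, its vertices are deleted, and the process repeats on the
successively smaller graphs until only singletons remain — a local
optimisation that prefers the biggest coherent family at every step.
Deleting vertices outside a cluster never invalidates it (both validity
levels are judged on the induced subgraph), so each emitted cluster is valid
in the residual graph at its emission step and in the original graph alike.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set

from .enumeration import CandidateList, enumerate_all
from .graph_model import (
    Cluster,
    EdgePartition,
    ScwibParams,
    SimilarityGraph,
    is_scwib,
    partition_edges,
)

__all__ = ["Decomposition", "decompose", "select_next", "graph_digest"]


def graph_digest(graph: SimilarityGraph) -> str:
    """Order-independent sha256 digest of a similarity graph's content."""
    h = hashlib.sha256()
    for v in sorted(graph.vertices):
        h.update(v.encode())
        h.update(b"\0")
    for a, b, w in sorted(
        (min(a, b), max(a, b), w) for a, b, w in graph.edges()
    ):
        h.update(f"{a}\t{b}\t{w:.10g}\n".encode())
    return h.hexdigest()


@dataclass
class Decomposition:
    """Ordered disjoint clusters plus residual singletons covering V.

    Cluster sizes are non-increasing along the list; provenance records the
    parameters, mode, rng seed and an input digest so a run can be checked
    against the graph it came from.
    """

    clusters: List[Cluster]
    singletons: List[str]
    provenance: Dict[str, object] = field(default_factory=dict)

    def covered_vertices(self) -> Set[str]:
        out: Set[str] = set(self.singletons)
        for c in self.clusters:
            out |= c.members
        return out

    def member_sets(self) -> List[FrozenSet[str]]:
        return [c.members for c in self.clusters]

    def validate(self) -> None:
        seen: Set[str] = set()
        prev = None
        for c in self.clusters:
            if c.members & seen:
                raise ValueError("clusters are not pairwise disjoint")
            seen |= c.members
            if prev is not None and len(c) > prev:
                raise ValueError("cluster sizes must be non-increasing")
            prev = len(c)
        if seen & set(self.singletons):
            raise ValueError("singleton listed inside a cluster")


def select_next(
    candidates: CandidateList,
    residual_vertices: Set[str],
    partition: Optional[EdgePartition] = None,
) -> Cluster:
    """Deterministically pick the next cluster to emit.

    Among candidates fully inside the residual vertex set, maximise in
    order: member count, total weight of internal edges at level W and
    above, then lexicographically smallest sorted member list.  Raises
    ``LookupError`` when no candidate survives the filter, signalling that
    the caller should emit the remaining vertices as singletons.
    """
    best: Optional[Cluster] = None
    best_key = None
    for c in candidates:
        if not c.members <= residual_vertices:
            continue
        weight = c.internal_weight
        key = (-len(c), -weight, tuple(sorted(c.members)))
        if best is None or key < best_key:
            best, best_key = c, key
    if best is None:
        raise LookupError("no candidate cluster survives the residual filter")
    return best


def decompose(
    graph: SimilarityGraph,
    params: ScwibParams,
    mode: str = "exact",
    budget: Optional[int] = None,
    rng_seed: int = 0,
    reorder_every: int = 1000,
    last_vertex_only: bool = False,
) -> Decomposition:
    """Largest-first disjoint decomposition.

    Each round enumerates candidates on the residual graph, emits the
    winner of :func:`select_next`, re-validates it against the residual
    graph, and deletes its vertices.  Vertices never absorbed into a
    multi-member cluster (including genes whose only similarities fell
    below the W filter) are reported as singletons.
    """
    residual: Set[str] = set(graph.vertices)
    clusters: List[Cluster] = []
    round_idx = 0
    while True:
        sub = graph.subgraph(residual)
        candidates = enumerate_all(
            sub,
            params,
            mode=mode,
            budget=budget,
            rng_seed=rng_seed + round_idx,
            reorder_every=reorder_every,
            last_vertex_only=last_vertex_only,
        )
        multi = CandidateList()
        for c in candidates:
            if len(c) >= 2:
                multi.add(c)
        if len(multi) == 0:
            break
        best = select_next(multi, residual)
        res_partition = partition_edges(sub, params)
        if not is_scwib(best.members, res_partition, params):
            raise AssertionError(
                f"emitted cluster fails re-validation: {sorted(best.members)}"
            )
        clusters.append(best)
        residual -= best.members
        round_idx += 1

    decomp = Decomposition(
        clusters=clusters,
        singletons=sorted(residual),
        provenance={
            "U": params.U,
            "W": params.W,
            "s": params.s,
            "mode": mode,
            "budget": budget,
            "rng_seed": rng_seed,
            "input_digest": graph_digest(graph),
        },
    )
    decomp.validate()
    return decomp
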