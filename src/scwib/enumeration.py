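"""Enumeration of candidate gene families by queue-based growth.

Every valid cluster is reachable (up to the non-hereditary caveat below) by
growing from a single seed vertex: a queue starts with the singleton seed
and each dequeued set is extended by outside vertices that attach to the
current set through a strong edge, keeping only extensions that are
themselves valid clusters.  A per-seed maximum-size bound derived from the
S-plex condition prunes extensions that could never validate.

Because the S-plex slack grows with cluster size, validity is not
hereditary: a valid set can, in rare configurations, have no chain of valid
subsets leading to it.  Growth through valid intermediates is faithful to
the cluster definition's constructive reading; the brute-force oracle in
:mod:`scwib.graph_model` measures the (rare) divergence instead of hiding it.

The outer driver processes seeds in increasing-degree order and removes each
seed once its families are listed, so each cluster is discovered from its
lowest-ordered member only.
"""

from __future__ import annotations

import math
import random
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Set, Tuple

from .graph_model import (
    Cluster,
    EdgePartition,
    ScwibParams,
    SimilarityGraph,
    is_scwib,
    partition_edges,
)

__all__ = [
    "CandidateList",
    "max_cluster_size_bound",
    "list_gene_family",
    "enumerate_all",
]


def max_cluster_size_bound(
    seed_degree: int, s: float, use_printed_bound: bool = False
) -> int:
    """Largest cluster size a vertex of total degree ``seed_degree`` can join.

    A member of a size-N cluster needs within-cluster degree at least
    (1-s)*N - 1; since within-cluster degree cannot exceed the vertex's
    total degree d (over edges at level W and above), the largest feasible
    size is m = floor((d + 1) / (1 - s)).

    ``use_printed_bound`` switches to the alternative m = floor(d*s + 1),
    kept only for comparison; it is not implied by the S-plex condition
    (as s -> 0 it collapses to 1 while clusters approach (d+1)-cliques).
    """
    if seed_degree < 0:
        raise ValueError("degree must be non-negative")
    if use_printed_bound:
        return int(math.floor(seed_degree * s + 1 + 1e-9))
    return int(math.floor((seed_degree + 1) / (1.0 - s) + 1e-9))


class CandidateList:
    """Deduplicated collection of discovered clusters, insertion-ordered."""

    def __init__(self) -> None:
        self._by_members: Dict[FrozenSet[str], Cluster] = {}

    def add(self, cluster: Cluster) -> None:
        self._by_members.setdefault(cluster.members, cluster)

    def extend(self, other: "CandidateList") -> None:
        for c in other:
            self.add(c)

    def member_sets(self) -> Set[FrozenSet[str]]:
        return set(self._by_members)

    def __contains__(self, members: FrozenSet[str]) -> bool:
        return frozenset(members) in self._by_members

    def __iter__(self) -> Iterator[Cluster]:
        return iter(self._by_members.values())

    def __len__(self) -> int:
        return len(self._by_members)


def _strong_frontier(
    members: Tuple[str, ...],
    partition: EdgePartition,
    allowed: Set[str],
    last_vertex_only: bool,
) -> List[str]:
    """Outside vertices joined by a strong edge to the growing set."""
    mset = set(members)
    sources = members[-1:] if last_vertex_only else members
    out: Set[str] = set()
    for v in sources:
        for u in partition.strong.neighbors(v):
            if u not in mset and u in allowed:
                out.add(u)
    return sorted(out)


def list_gene_family(
    seed: str,
    partition: EdgePartition,
    params: ScwibParams,
    mode: str = "exact",
    budget: Optional[int] = None,
    rng: Optional[random.Random] = None,
    allowed: Optional[Set[str]] = None,
    last_vertex_only: bool = False,
    use_printed_bound: bool = False,
    use_size_bound: bool = True,
) -> CandidateList:
    """All growth-reachable valid clusters containing ``seed``.

    Breadth-first growth from the singleton seed: each popped state is
    recorded, and while below the seed's maximum-size bound, every strong
    neighbour of the current set is tried; an extension is enqueued only if
    the extended set is itself a valid cluster.

    mode
        ``"exact"`` explores all expansion paths (with member-set
        deduplication); ``"heuristic"`` samples at most ``budget``
        admissible extensions per expansion step, uniformly without
        replacement, using ``rng``.
    allowed
        restricts growth to a vertex subset (used by the outer driver and
        the greedy decomposition); defaults to the whole graph.
    last_vertex_only
        reproduce the literal growth rule that extends only from the most
        recently added vertex; off by default because that rule cannot
        reach some clusters the definition admits (e.g. a star grown
        leaf-after-leaf).
    use_size_bound
        disable only to verify that the bound never prunes a valid cluster.
    """
    if allowed is None:
        allowed = set(partition.wplus.nodes)
    if seed not in allowed:
        raise KeyError(f"seed vertex {seed!r} not in graph")
    if mode not in ("exact", "heuristic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "heuristic":
        if budget is None or budget <= 0:
            raise ValueError("heuristic mode requires a positive budget")
        if rng is None:
            rng = random.Random(0)

    d = sum(1 for u in partition.wplus.neighbors(seed) if u in allowed)
    m = (
        max_cluster_size_bound(d, params.s, use_printed_bound=use_printed_bound)
        if use_size_bound
        else len(allowed)
    )

    results = CandidateList()
    # dedup key: member set alone when growth is order-free; (set, last
    # vertex) under the literal rule, where the frontier depends on order.
    seen: Set[object] = set()
    queue: deque[Tuple[str, ...]] = deque()
    start = (seed,)
    queue.append(start)
    seen.add(frozenset(start) if not last_vertex_only else (frozenset(start), seed))

    while queue:
        sg = queue.popleft()
        mset = frozenset(sg)
        if mset not in results:
            results.add(Cluster.from_members(mset, partition))
        if len(sg) >= m:
            continue
        frontier = _strong_frontier(sg, partition, allowed, last_vertex_only)
        if mode == "heuristic" and len(frontier) > budget:
            frontier = sorted(rng.sample(frontier, budget))
        for u in frontier:
            new_members = mset | {u}
            key: object = (
                new_members if not last_vertex_only else (new_members, u)
            )
            if key in seen:
                continue
            seen.add(key)
            if is_scwib(new_members, partition, params):
                queue.append(sg + (u,))
    return results


def enumerate_all(
    graph: SimilarityGraph,
    params: ScwibParams,
    mode: str = "exact",
    budget: Optional[int] = None,
    rng_seed: int = 0,
    reorder_every: int = 1000,
    last_vertex_only: bool = False,
    use_printed_bound: bool = False,
    use_size_bound: bool = True,
) -> CandidateList:
    """Enumerate candidate clusters over the whole graph.

    Vertices are processed in increasing degree (ties broken by identifier);
    each seed's families are listed, the seed is removed, and the order is
    refreshed every ``reorder_every`` removals.  The union of the returned
    member sets, which always includes every singleton, covers V.
    """
    partition = partition_edges(graph, params)
    rng = random.Random(rng_seed)
    remaining: Set[str] = set(graph.vertices)
    results = CandidateList()

    order: List[str] = []
    removals_since_sort = reorder_every  # force an initial sort

    while remaining:
        if removals_since_sort >= reorder_every or not order:
            deg = {
                v: sum(1 for u in partition.wplus.neighbors(v) if u in remaining)
                for v in remaining
            }
            order = sorted(remaining, key=lambda v: (deg[v], v))
            removals_since_sort = 0
        v = next(x for x in order if x in remaining)
        results.extend(
            list_gene_family(
                v,
                partition,
                params,
                mode=mode,
                budget=budget,
                rng=rng,
                allowed=remaining,
                last_vertex_only=last_vertex_only,
                use_printed_bound=use_printed_bound,
                use_size_bound=use_size_bound,
            )
        )
        remaining.discard(v)
        removals_since_sort += 1
    return results
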