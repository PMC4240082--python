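"""Core data model for soft-clique-with-backbone (SCWiB) clustering.

A gene family is modelled as a vertex set in a weighted similarity graph
that is valid on two levels:

* **backbone connectivity** — the set must be connected using only *strong*
  edges, i.e. pairwise similarities at or above the upper threshold ``U``;
* **S-plex density** — counting all edges at or above the lower threshold
  ``W`` (strong or weak), every member of a set of size ``N`` must have
  within-set degree at least ``N - S`` where ``S = s*N + 1``.

The proportional slack ``S`` is what lets large families tolerate a few
missing similarities while still forbidding the chaining artefact of
single-linkage-style clustering: a long path of pairwise-similar genes can
never validate as one family because its interior offers no density support.

This module holds the parameter and graph containers, the two-level edge
classification, the validity predicate, and a brute-force enumerator used as
an independent oracle in the test-suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Set, Tuple

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ScwibParams",
    "SimilarityGraph",
    "EdgePartition",
    "Cluster",
    "ScwibCheck",
    "partition_edges",
    "splex_min_degree",
    "is_backbone_connected",
    "is_scwib",
    "scwib_check",
    "brute_force_scwibs",
]

#: tiny slack for comparing an integer degree with the real-valued S-plex
#: bound; guards against float representation of (1-s)*N - 1 only, never
#: changes a verdict for exactly representable bounds.
_EPS = 1e-9


@dataclass(frozen=True)
class ScwibParams:
    """The (U, W, s) parameter triple.

    U
        strong-edge similarity threshold; backbone connectivity is judged on
        edges with weight >= U (inclusive).
    W
        weak-edge similarity threshold; S-plex degrees count edges with
        weight >= W (inclusive).  Pairs below W are discarded outright.
    s
        tolerance coefficient in (0, 1); the allowed slack is S = s*N + 1
        for a cluster of size N.

    Defaults are the operating point used throughout: U=0.7, W=0.6, s=0.25.
    """

    U: float = 0.7
    W: float = 0.6
    s: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.W < self.U < 1.0):
            raise ValueError(
                f"thresholds must satisfy 0 < W < U < 1, got W={self.W}, U={self.U}"
            )
        if not (0.0 < self.s < 1.0):
            raise ValueError(f"tolerance coefficient must be in (0, 1), got s={self.s}")


class SimilarityGraph:
    """Undirected weighted graph of pairwise gene similarities.

    Vertices are opaque string identifiers; each unordered pair carries at
    most one weight in [0, 1].  Self-loops are rejected.  Duplicate pair
    records (as emitted by both orientations of an all-vs-all comparison)
    are resolved to the maximum weight with a logged warning when the two
    weights disagree.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[Tuple[str, str, float]], vertices: Iterable[str] = ()
    ) -> "SimilarityGraph":
        g = cls()
        for v in vertices:
            g.add_vertex(v)
        for a, b, w in edges:
            g.add_edge(a, b, w)
        return g

    def add_vertex(self, v: str) -> None:
        self._g.add_node(v)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on vertex {a!r} is not allowed")
        if not (0.0 <= weight <= 1.0):
            raise ValueError(
                f"similarity for pair ({a!r}, {b!r}) must lie in [0, 1], got {weight}"
            )
        if self._g.has_edge(a, b):
            old = self._g[a][b]["weight"]
            if old != weight:
                logger.warning(
                    "duplicate pair (%s, %s) with conflicting weights %s and %s; keeping max",
                    a, b, old, weight,
                )
            weight = max(old, weight)
        self._g.add_edge(a, b, weight=weight)

    # -- inspection -------------------------------------------------------

    @property
    def vertices(self) -> Set[str]:
        return set(self._g.nodes)

    def __contains__(self, v: str) -> bool:
        return v in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def weight(self, a: str, b: str) -> float:
        return self._g[a][b]["weight"]

    def edges(self) -> Iterator[Tuple[str, str, float]]:
        for a, b, data in self._g.edges(data=True):
            yield a, b, data["weight"]

    def subgraph(self, vertices: Iterable[str]) -> "SimilarityGraph":
        """Induced subgraph as a new, independent SimilarityGraph."""
        keep = set(vertices)
        unknown = keep - self.vertices
        if unknown:
            raise KeyError(f"unknown vertices: {sorted(unknown)}")
        out = SimilarityGraph()
        out._g = self._g.subgraph(keep).copy()
        return out

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityGraph):
            return NotImplemented
        return nx.utils.graphs_equal(self._g, other._g)


@dataclass
class EdgePartition:
    """Two-level classification of a similarity graph's edges.

    ``strong`` holds the backbone graph (edges with weight >= U);
    ``wplus`` holds the density graph (edges with weight >= W, i.e. the
    union of strong and weak edges).  Both graphs carry every vertex of the
    source graph so that isolated vertices keep well-defined degrees.
    """

    strong: nx.Graph
    wplus: nx.Graph
    params: ScwibParams
    n_dropped: int = 0

    @property
    def n_strong(self) -> int:
        return self.strong.number_of_edges()

    @property
    def n_weak(self) -> int:
        return self.wplus.number_of_edges() - self.strong.number_of_edges()

    @property
    def vertices(self) -> Set[str]:
        return set(self.wplus.nodes)

    def strong_edges(self) -> Set[FrozenSet[str]]:
        return {frozenset(e) for e in self.strong.edges()}

    def weak_edges(self) -> Set[FrozenSet[str]]:
        return {frozenset(e) for e in self.wplus.edges()} - self.strong_edges()

    def restricted(self, vertices: Iterable[str]) -> "EdgePartition":
        """Partition induced on a vertex subset (copies, safe to keep)."""
        keep = set(vertices)
        return EdgePartition(
            strong=self.strong.subgraph(keep).copy(),
            wplus=self.wplus.subgraph(keep).copy(),
            params=self.params,
            n_dropped=0,
        )


def partition_edges(graph: SimilarityGraph, params: ScwibParams) -> EdgePartition:
    """Classify every edge as strong (w >= U), weak (W <= w < U) or dropped.

    Every retained edge lands in exactly one class; edges below W are
    discarded (their count is kept for reporting).  Raises ``ValueError``
    naming the offending pair if a weight lies outside [0, 1].
    """
    strong = nx.Graph()
    wplus = nx.Graph()
    strong.add_nodes_from(graph.vertices)
    wplus.add_nodes_from(graph.vertices)
    dropped = 0
    for a, b, w in graph.edges():
        if not (0.0 <= w <= 1.0):
            raise ValueError(f"malformed weight {w} on pair ({a!r}, {b!r})")
        if w >= params.U:
            strong.add_edge(a, b, weight=w)
            wplus.add_edge(a, b, weight=w)
        elif w >= params.W:
            wplus.add_edge(a, b, weight=w)
        else:
            dropped += 1
    return EdgePartition(strong=strong, wplus=wplus, params=params, n_dropped=dropped)


def splex_min_degree(N: int, s: float) -> float:
    """Real-valued minimum within-cluster degree for a cluster of size N.

    With S = s*N + 1 the requirement "degree at least N - S" becomes
    degree >= (1-s)*N - 1.  The bound is returned as a real number and the
    integer degree is compared against it directly — no rounding of S.
    """
    if N < 1:
        raise ValueError(f"cluster size must be >= 1, got {N}")
    return (1.0 - s) * N - 1.0


def _require_known(members: Iterable[str], partition: EdgePartition) -> Set[str]:
    mset = set(members)
    if not mset:
        raise ValueError("member set must be nonempty")
    unknown = mset - set(partition.wplus.nodes)
    if unknown:
        raise KeyError(f"unknown vertices: {sorted(unknown)}")
    return mset


def is_backbone_connected(members: Iterable[str], partition: EdgePartition) -> bool:
    """True iff the member set is connected using strong edges alone.

    A singleton is connected by convention.  Weak edges never contribute to
    the backbone.
    """
    mset = _require_known(members, partition)
    sub = partition.strong.subgraph(mset)
    return nx.is_connected(sub)


@dataclass(frozen=True)
class ScwibCheck:
    """Validity certificate: verdict plus per-vertex S-plex degree margins.

    ``margins[v]`` is (within-cluster degree at level W) minus the S-plex
    bound; a negative margin identifies a failing vertex.
    """

    valid: bool
    backbone_connected: bool
    margins: Mapping[str, float]

    def __bool__(self) -> bool:
        return self.valid


def scwib_check(
    members: Iterable[str], partition: EdgePartition, params: ScwibParams
) -> ScwibCheck:
    """Full two-level validity check with per-vertex margins."""
    mset = _require_known(members, partition)
    n = len(mset)
    bound = splex_min_degree(n, params.s)
    dens = partition.wplus.subgraph(mset)
    margins = {v: dens.degree(v) - bound for v in mset}
    splex_ok = all(m >= -_EPS for m in margins.values())
    connected = is_backbone_connected(mset, partition)
    return ScwibCheck(valid=connected and splex_ok, backbone_connected=connected, margins=margins)


def is_scwib(
    members: Iterable[str], partition: EdgePartition, params: ScwibParams
) -> bool:
    """True iff the member set is a valid soft clique with backbone."""
    return scwib_check(members, partition, params).valid


@dataclass(frozen=True)
class Cluster:
    """A validated vertex set with cached certificate data.

    The cached fields (``splex_degrees``, ``backbone_edges``,
    ``internal_weight``) are conveniences; validity is always recomputable
    from ``members`` plus the graph and parameters, and recomputation is
    authoritative.
    """

    members: FrozenSet[str]
    splex_degrees: Mapping[str, int] = field(default_factory=dict, compare=False)
    backbone_edges: FrozenSet[FrozenSet[str]] = field(default=frozenset(), compare=False)
    internal_weight: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("a cluster has at least one member")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    @classmethod
    def from_members(
        cls, members: Iterable[str], partition: EdgePartition
    ) -> "Cluster":
        mset = frozenset(members)
        dens = partition.wplus.subgraph(mset)
        back = partition.strong.subgraph(mset)
        return cls(
            members=mset,
            splex_degrees={v: dens.degree(v) for v in mset},
            backbone_edges=frozenset(frozenset(e) for e in back.edges()),
            internal_weight=sum(d["weight"] for _, _, d in dens.edges(data=True)),
        )


def brute_force_scwibs(
    graph: SimilarityGraph,
    params: ScwibParams,
    max_size: int | None = None,
    vertex_cap: int = 20,
) -> Set[FrozenSet[str]]:
    """All valid SCWiB vertex subsets by direct subset enumeration.

    Exact and order-independent; meant as a test oracle on small graphs.
    Refuses graphs with more than ``vertex_cap`` vertices.
    """
    verts = sorted(graph.vertices)
    if len(verts) > vertex_cap:
        raise ValueError(
            f"brute force refused: {len(verts)} vertices exceeds cap {vertex_cap}"
        )
    if max_size is None:
        max_size = len(verts)
    partition = partition_edges(graph, params)
    out: Set[FrozenSet[str]] = set()
    for k in range(1, max_size + 1):
        for combo in itertools.combinations(verts, k):
            if is_scwib(combo, partition, params):
                out.add(frozenset(combo))
    return out
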