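"""Reading similarity-pair files and cluster files; writing decompositions.

The pair reader consumes the tab- or whitespace-delimited output of
all-vs-all self-comparison pipelines (BLAST tabular / SynMap exports): the
first three usable columns are taken as (gene_a, gene_b, similarity) and any
extra columns are ignored.  Similarities may be on the percent scale
(0, 100] or the fraction scale (0, 1]; by default any value above 1 flags
the whole file as percent-scale and everything is divided by 100.

Cluster files use the MCL output dialect — one cluster per line,
tab-separated member identifiers — so decompositions written here and
clusters produced by external tools flow through the same comparison code.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import FrozenSet, List, Optional, Union

from .decomposition import Decomposition
from .graph_model import SimilarityGraph

logger = logging.getLogger(__name__)

__all__ = ["read_pairs", "read_mcl_clusters", "write_decomposition"]

PathLike = Union[str, Path]


def read_pairs(
    path: PathLike,
    min_similarity: float = 0.6,
    unit: str = "auto",
) -> SimilarityGraph:
    """Read a pairwise-similarity list into a :class:`SimilarityGraph`.

    Lines starting with ``#`` and blank lines are skipped.  Self-pairs are
    dropped (with a logged count), pairs below ``min_similarity`` (on the
    fraction scale) are dropped, and duplicate pairs are resolved to the
    maximum weight.  ``unit`` is ``"auto"`` (percent iff any value > 1),
    ``"percent"`` or ``"fraction"``.

    An empty file yields an empty graph; an unparsable similarity raises
    ``ValueError`` with the line number.
    """
    if unit not in ("auto", "percent", "fraction"):
        raise ValueError(f"unknown unit {unit!r}")
    records: List[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 3 columns, got {len(fields)}"
                )
            a, b, raw = fields[0], fields[1], fields[2]
            try:
                sim = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparsable similarity {raw!r}"
                ) from exc
            if sim <= 0:
                raise ValueError(
                    f"{path}:{lineno}: similarity must be positive, got {sim}"
                )
            records.append((a, b, sim))

    percent = unit == "percent" or (
        unit == "auto" and any(sim > 1.0 for _, _, sim in records)
    )
    if percent:
        records = [(a, b, sim / 100.0) for a, b, sim in records]

    graph = SimilarityGraph()
    n_self = 0
    n_below = 0
    for a, b, sim in records:
        if a == b:
            n_self += 1
            continue
        if sim < min_similarity:
            n_below += 1
            continue
        graph.add_edge(a, b, sim)
    if n_self:
        logger.info("dropped %d self-pairs", n_self)
    if n_below:
        logger.info(
            "dropped %d pairs below min similarity %s", n_below, min_similarity
        )
    return graph


def read_mcl_clusters(path: PathLike) -> List[FrozenSet[str]]:
    """Read an MCL-dialect cluster file: one cluster per line, tab-separated.

    Blank lines and ``#`` comment lines are skipped.  The clusters must be
    disjoint; a gene appearing on two lines raises ``ValueError`` naming it.
    """
    clusters: List[FrozenSet[str]] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            members = [f for f in line.split("\t") if f]
            for g in members:
                if g in seen:
                    raise ValueError(
                        f"{path}:{lineno}: gene {g!r} already assigned on line {seen[g]}"
                    )
                seen[g] = lineno
            clusters.append(frozenset(members))
    return clusters


def write_decomposition(decomposition: Decomposition, path: PathLike) -> None:
    """Write a decomposition as an MCL-compatible cluster file.

    A ``#``-prefixed header records provenance (U, W, s, mode, rng seed,
    input digest); then one cluster per line in emission order with sorted,
    tab-separated member identifiers.  The result round-trips losslessly
    through :func:`read_mcl_clusters`.
    """
    decomposition.validate()
    prov = decomposition.provenance
    with open(path, "w") as fh:
        fh.write("# scwib decomposition\n")
        for key in ("U", "W", "s", "mode", "budget", "rng_seed", "input_digest"):
            if key in prov:
                fh.write(f"# {key}: {prov[key]}\n")
        fh.write(f"# clusters: {len(decomposition.clusters)}\n")
        fh.write(f"# singletons: {len(decomposition.singletons)}\n")
        for cluster in decomposition.clusters:
            fh.write("\t".join(sorted(cluster.members)) + "\n")
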