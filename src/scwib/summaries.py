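"""Family-size-distribution statistics and two-way comparisons.

Families are tallied into inclusive integer size bins, both by family count
and by gene count (size × families).  Singletons are excluded by default,
matching how gene-family size spectra are conventionally reported.  The
comparison helper reports per-bin proportion differences and flags the
pattern where one input has strictly lower proportions in every bin at or
above a configurable "moderate" size — the signature of a genome depleted
in moderate and large families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "DEFAULT_BINS",
    "SizeBin",
    "SizeDistribution",
    "size_distribution",
    "ComparisonResult",
    "compare_distributions",
]

#: inclusive (low, high) ranges; ``None`` marks the open-ended top bin.
SizeBin = Tuple[int, Optional[int]]

#: Default scheme: singles per size up to 7, then 8-10, 11-13, 14-17,
#: 18-21, 22-26 and an open-ended 27+ bin for the largest families.
DEFAULT_BINS: Tuple[SizeBin, ...] = (
    (2, 2), (3, 3), (4, 4), (5, 5), (6, 6), (7, 7),
    (8, 10), (11, 13), (14, 17), (18, 21), (22, 26), (27, None),
)

#: index of the first "moderate" bin (8-10) in the default scheme.
DEFAULT_MODERATE_BIN: SizeBin = (8, 10)


def bin_label(b: SizeBin) -> str:
    lo, hi = b
    if hi is None:
        return f"{lo}+"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


def _validate_bins(bins: Sequence[SizeBin]) -> None:
    if not bins:
        raise ValueError("at least one bin is required")
    prev_hi = 0
    for i, (lo, hi) in enumerate(bins):
        if lo <= prev_hi:
            raise ValueError(f"bins must be disjoint and increasing at {bin_label((lo, hi))}")
        if hi is not None:
            if hi < lo:
                raise ValueError(f"bin {bin_label((lo, hi))} is empty")
            prev_hi = hi
        else:
            if i != len(bins) - 1:
                raise ValueError("only the final bin may be open-ended")
            prev_hi = float("inf")  # type: ignore[assignment]
    if bins[-1][1] is not None:
        raise ValueError("the final bin must be open-ended")


@dataclass
class SizeDistribution:
    """Per-bin family and gene counts with derived proportions."""

    bins: Tuple[SizeBin, ...]
    family_counts: Tuple[int, ...]
    gene_counts: Tuple[int, ...]
    total_families: int
    total_genes: int
    excluded_singletons: int
    singletons_excluded: bool = True

    @property
    def family_proportions(self) -> Tuple[float, ...]:
        t = self.total_families
        return tuple(c / t if t else 0.0 for c in self.family_counts)

    @property
    def gene_proportions(self) -> Tuple[float, ...]:
        t = self.total_genes
        return tuple(c / t if t else 0.0 for c in self.gene_counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": [bin_label(b) for b in self.bins],
                "families": self.family_counts,
                "genes": self.gene_counts,
                "family_proportion": self.family_proportions,
                "gene_proportion": self.gene_proportions,
            }
        )


def size_distribution(
    clusters: Iterable[Iterable[str]],
    bins: Sequence[SizeBin] = DEFAULT_BINS,
    include_singletons: bool = False,
) -> SizeDistribution:
    """Tally disjoint clusters into a size distribution.

    Singletons are excluded unless ``include_singletons`` is set, in which
    case a ``(1, 1)`` bin is prepended when the scheme does not cover
    size 1.  Overlapping clusters are rejected.
    """
    sets: List[FrozenSet[str]] = [frozenset(c) for c in clusters]
    seen: set[str] = set()
    for c in sets:
        if c & seen:
            raise ValueError(f"clusters overlap on {sorted(c & seen)}")
        seen |= c

    bins = tuple(bins)
    if include_singletons and bins[0][0] > 1:
        bins = ((1, 1),) + bins
    _validate_bins(bins)

    excluded_singletons = 0
    fam = [0] * len(bins)
    gen = [0] * len(bins)
    for c in sets:
        n = len(c)
        if n == 1 and not include_singletons:
            excluded_singletons += 1
            continue
        for i, (lo, hi) in enumerate(bins):
            if n >= lo and (hi is None or n <= hi):
                fam[i] += 1
                gen[i] += n
                break
        else:
            raise ValueError(f"cluster size {n} falls outside the bin scheme")
    return SizeDistribution(
        bins=bins,
        family_counts=tuple(fam),
        gene_counts=tuple(gen),
        total_families=sum(fam),
        total_genes=sum(gen),
        excluded_singletons=excluded_singletons,
        singletons_excluded=not include_singletons,
    )


@dataclass
class ComparisonResult:
    """Per-bin differences (a minus b) plus depletion flags.

    ``a_deficit_families`` is true when distribution *a* has strictly lower
    family proportion than *b* in every bin at or above the moderate bin
    (likewise ``a_deficit_genes`` for gene proportions, and the ``b_*``
    flags for the opposite direction).
    """

    table: pd.DataFrame
    moderate_bin: SizeBin
    a_deficit_families: bool
    a_deficit_genes: bool
    b_deficit_families: bool
    b_deficit_genes: bool


def compare_distributions(
    dist_a: SizeDistribution,
    dist_b: SizeDistribution,
    moderate_bin: SizeBin = DEFAULT_MODERATE_BIN,
) -> ComparisonResult:
    """Compare two distributions sharing one bin scheme."""
    if dist_a.bins != dist_b.bins:
        raise ValueError("bin schemes differ; distributions are not comparable")
    if moderate_bin not in dist_a.bins:
        raise ValueError(f"moderate bin {bin_label(moderate_bin)} not in the scheme")
    start = dist_a.bins.index(moderate_bin)

    fa, fb = dist_a.family_proportions, dist_b.family_proportions
    ga, gb = dist_a.gene_proportions, dist_b.gene_proportions
    table = pd.DataFrame(
        {
            "bin": [bin_label(b) for b in dist_a.bins],
            "family_proportion_a": fa,
            "family_proportion_b": fb,
            "family_proportion_diff": [x - y for x, y in zip(fa, fb)],
            "gene_proportion_a": ga,
            "gene_proportion_b": gb,
            "gene_proportion_diff": [x - y for x, y in zip(ga, gb)],
        }
    )
    upper = range(start, len(dist_a.bins))
    return ComparisonResult(
        table=table,
        moderate_bin=moderate_bin,
        a_deficit_families=all(fa[i] < fb[i] for i in upper),
        a_deficit_genes=all(ga[i] < gb[i] for i in upper),
        b_deficit_families=all(fb[i] < fa[i] for i in upper),
        b_deficit_genes=all(gb[i] < ga[i] for i in upper),
    )
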