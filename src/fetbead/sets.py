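"""DEG-set comparison: Venn partitioning and overlap enrichment.

A Venn *region* is the subset of identifiers belonging to exactly one
membership signature across the input sets (e.g. "in A and B but not C").
Regions are pairwise disjoint and jointly cover the union, so region counts
are the numbers printed inside a Venn diagram.

Overlap with an external gene list is tested with the one-sided
hypergeometric upper tail (Fisher's exact test in the enrichment
direction): drawing ``n`` targets from a universe of ``N`` identifiers of
which ``m`` are DEGs, ``p = P(X >= k)`` for the observed overlap ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom

def venn_partition(sets: Mapping[str, Iterable[str]]) -> dict[frozenset, set]:
    """Partition 2-4 named sets into their exact membership regions.

    Returns a map from region signature (frozenset of set names) to the
    identifiers lying in exactly those sets.  Empty regions are omitted.
    """
    if hasattr(sets, "keys"):
        named = {str(k): set(v) for k, v in sets.items()}
        if len(named) != len(sets):
            raise ValueError("duplicate set names")
    else:
        pairs = list(sets)
        names = [str(k) for k, _ in pairs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate set names")
        named = {str(k): set(v) for k, v in pairs}
    if not 2 <= len(named) <= 4:
        raise ValueError(f"expected 2-4 sets, got {len(named)}")
    regions: dict[frozenset, set] = {}
    universe = set().union(*named.values())
    for ident in universe:
        signature = frozenset(name for name, ids in named.items() if ident in ids)
        regions.setdefault(signature, set()).add(ident)
    return regions


@dataclass
class CombinedComparison:
    """Region-wise overlap of single-knockdown DEG regions with a combined set.

    ``region_overlap`` maps each Venn region of the single sets to
    ``(n_in_combined, region_size)``; ``combined_unique`` counts combined-set
    members absent from every single set.
    """

    region_overlap: dict[frozenset, tuple[int, int]]
    combined_unique: int
    combined_total: int


def compare_to_combined(
    singles: Mapping[str, Iterable[str]], combined: Iterable[str]
) -> CombinedComparison:
    """Compare single-knockdown DEG regions against a combined-knockdown set."""
    combined_set = set(combined)
    regions = venn_partition(singles)
    overlap = {
        sig: (len(ids & combined_set), len(ids)) for sig, ids in regions.items()
    }
    union = set().union(*(ids for ids in regions.values())) if regions else set()
    return CombinedComparison(
        region_overlap=overlap,
        combined_unique=len(combined_set - union),
        combined_total=len(combined_set),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    k: int
    m: int
    n: int
    universe: int
    expected: float
    p_value: float
    test: str = "hypergeometric upper tail (one-sided)"


def enrichment_test(
    deg_set: Iterable[str],
    target_set: Iterable[str],
    universe_size: int,
    case_fold: bool = False,
) -> EnrichmentResult:
    """One-sided hypergeometric overlap test between two identifier sets.

    ``universe_size`` is the number of identifiers that could have appeared
    in either set — for probe-level DEG analyses, the number of probes
    surviving the detection filter.  Identifier matching is exact-string
    unless ``case_fold`` is set.
    """
    degs = {s.casefold() for s in deg_set} if case_fold else set(deg_set)
    targets = {s.casefold() for s in target_set} if case_fold else set(target_set)
    union = degs | targets
    if universe_size < len(union):
        raise ValueError(
            f"universe ({universe_size}) smaller than the union of the sets "
            f"({len(union)})"
        )
    k = len(degs & targets)
    m, n, N = len(degs), len(targets), int(universe_size)
    expected = m * n / N if N else 0.0
    # P(X >= k) with X ~ Hypergeom(N, m, n)
    p = float(hypergeom.sf(k - 1, N, m, n))
    return EnrichmentResult(k=k, m=m, n=n, universe=N, expected=expected, p_value=min(p, 1.0))
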