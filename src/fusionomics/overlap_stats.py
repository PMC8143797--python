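"""Hypergeometric enrichment machinery and gene-set partitioning.

The overlap-strength statistic used throughout the pipeline is the
hypergeometric density (HGD): for an observed overlap of k identifiers
between a query set of size n and a reference set of size K drawn from a
population of N genes,

    HGD = -log10 P(X = k),   X ~ Hypergeometric(N, K, n),

reported alongside the enrichment tail probability P(X >= k).  All
combinatorics are computed in log-gamma space so overlaps whose densities
underflow double precision (HGD >> 300) remain representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Iterable, Literal, Mapping

from scipy.special import gammaln, logsumexp

__all__ = [
    "OverlapTest",
    "VennPartition",
    "hypergeom_logpmf",
    "hypergeom_pmf",
    "hypergeom_tail",
    "hgd",
    "overlap_test",
    "venn_partition",
    "overlap_fraction",
]

LOG10_E = math.log10(math.e)


def _validate(k: int, K: int, n: int, N: int) -> None:
    if min(k, K, n, N) < 0:
        raise ValueError(f"negative argument in (k={k}, K={K}, n={n}, N={N})")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")


def hypergeom_logpmf(k: int, K: int, n: int, N: int) -> float:
    """Natural-log hypergeometric pmf; -inf for impossible configurations."""
    _validate(k, K, n, N)
    if k > min(K, n) or n - k > N - K or k < 0:
        return -math.inf
    # log C(K,k) + log C(N-K, n-k) - log C(N,n)
    def logcomb(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logcomb(K, k) + logcomb(N - K, n - k) - logcomb(N, n)


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """P(X = k): probability that n draws without replacement from a
    population of N containing K successes yield exactly k successes."""
    lp = hypergeom_logpmf(k, K, n, N)
    return 0.0 if lp == -math.inf else math.exp(lp)


def hypergeom_tail(
    k: int, K: int, n: int, N: int, mode: Literal["inclusive", "exclusive"] = "inclusive"
) -> float:
    """Enrichment tail probability.

    ``inclusive`` (default) returns P(X >= k), the standard enrichment
    p-value; ``exclusive`` returns P(X > k) for bit-compatibility with
    upper-tail conventions that exclude the boundary.
    """
    _validate(k, K, n, N)
    lo = k if mode == "inclusive" else k + 1
    hi = min(K, n)
    if lo > hi:
        return 0.0
    logs = [hypergeom_logpmf(j, K, n, N) for j in range(lo, hi + 1)]
    logs = [lp for lp in logs if lp > -math.inf]
    if not logs:
        return 0.0
    return min(1.0, math.exp(logsumexp(logs)))


def hgd(k: int, K: int, n: int, N: int) -> float:
    """-log10 of the hypergeometric density; +inf for impossible overlaps."""
    lp = hypergeom_logpmf(k, K, n, N)
    if lp == -math.inf:
        return math.inf
    return max(0.0, -lp * LOG10_E)


@dataclass(frozen=True)
class OverlapTest:
    """A (k, K, n, N) overlap configuration with its derived statistics."""

    k: int
    K: int
    n: int
    N: int
    density: float
    tail_p: float
    hgd: float

    @classmethod
    def from_sets(
        cls,
        query: Iterable[Hashable],
        reference: Iterable[Hashable],
        population_size: int,
        tail_mode: Literal["inclusive", "exclusive"] = "inclusive",
    ) -> "OverlapTest":
        q, r = set(query), set(reference)
        return overlap_test(len(q & r), len(r), len(q), population_size, tail_mode)


def overlap_test(
    k: int, K: int, n: int, N: int,
    tail_mode: Literal["inclusive", "exclusive"] = "inclusive",
) -> OverlapTest:
    return OverlapTest(
        k=k, K=K, n=n, N=N,
        density=hypergeom_pmf(k, K, n, N),
        tail_p=hypergeom_tail(k, K, n, N, tail_mode),
        hgd=hgd(k, K, n, N),
    )


@dataclass(frozen=True)
class VennPartition:
    """Exclusive region counts for 2 or 3 labelled sets.

    ``regions`` maps each non-empty frozenset of labels to the number of
    elements belonging to exactly those sets.
    """

    labels: tuple[str, ...]
    regions: Mapping[frozenset, int]
    set_sizes: Mapping[str, int]
    union_size: int

    def region(self, *labels: str) -> int:
        return self.regions.get(frozenset(labels), 0)

    def exclusive_to(self, label: str) -> int:
        """Elements in ``label`` and no other set."""
        return self.region(label)


def venn_partition(sets: Mapping[str, Iterable[Hashable]]) -> VennPartition:
    """Partition 2 or 3 labelled sets into exclusive Venn regions."""
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn_partition supports 2 or 3 sets, got {len(sets)}")
    materialized = {label: set(items) for label, items in sets.items()}
    labels = tuple(materialized)
    union = set().union(*materialized.values())
    regions: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(materialized[l] for l in combo))
            outside = set().union(
                *(materialized[l] for l in labels if l not in combo), set()
            )
            regions[frozenset(combo)] = len(inside - outside)
    return VennPartition(
        labels=labels,
        regions=regions,
        set_sizes={l: len(s) for l, s in materialized.items()},
        union_size=len(union),
    )


def overlap_fraction(query: Iterable[Hashable], reference: Iterable[Hashable]) -> float:
    """Percentage of the query set also present in the reference set."""
    q = set(query)
    if not q:
        raise ValueError("overlap_fraction undefined for an empty query set")
    return 100.0 * len(q & set(reference)) / len(q)
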