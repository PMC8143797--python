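"""ATAC-side set construction: consensus peaks, baseline vs condition-unique
accessible genes, and the binding-affinity matrix behind the accessibility PCA.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomicInterval
from .overlap_stats import OverlapTest

__all__ = [
    "ConsensusPeakSet",
    "AccessibilityPartition",
    "build_consensus",
    "accessibility_partition",
    "affinity_matrix",
]


@dataclass(frozen=True)
class ConsensusPeakSet:
    """Merged intervals retained when present in >= min_overlap_samples samples."""

    intervals: tuple[GenomicInterval, ...]
    presence: np.ndarray  # intervals x samples boolean
    sample_names: tuple[str, ...]
    min_overlap_samples: int


@dataclass(frozen=True)
class AccessibilityPartition:
    baseline_genes: frozenset
    unique_genes: frozenset
    focal: str
    controls: tuple[str, ...]
    pairwise: dict[str, OverlapTest]


def _merge(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # touching intervals merge
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def build_consensus(
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
    min_overlap_samples: int = 2,
) -> ConsensusPeakSet:
    """Union-merge per-sample peaks, keep merged intervals supported by
    >= min_overlap_samples samples (>= 1 bp overlap counts as presence)."""
    samples = tuple(peak_sets)
    if len(samples) < 1:
        raise ValueError("need at least one sample")
    if min_overlap_samples > len(samples):
        raise ValueError(
            f"min_overlap_samples={min_overlap_samples} exceeds {len(samples)} samples"
        )
    merged = _merge([iv for ivs in peak_sets.values() for iv in ivs])
    presence = np.zeros((len(merged), len(samples)), dtype=bool)
    for si, sample in enumerate(samples):
        for iv in peak_sets[sample]:
            for mi, m in enumerate(merged):
                if m.chrom == iv.chrom and min(m.end, iv.end) - max(m.start, iv.start) >= 1:
                    presence[mi, si] = True
    keep = presence.sum(axis=1) >= min_overlap_samples
    return ConsensusPeakSet(
        intervals=tuple(m for m, k in zip(merged, keep) if k),
        presence=presence[keep],
        sample_names=samples,
        min_overlap_samples=min_overlap_samples,
    )


def accessibility_partition(
    condition_gene_sets: Mapping[str, set],
    focal: str,
    controls: Sequence[str],
    population_size: int | None = None,
) -> AccessibilityPartition:
    """Baseline = genes accessible in the focal condition and every control;
    unique = focal genes absent from all controls.  Pairwise hypergeometric
    overlap statistics against each control are attached when a population
    size is given."""
    for label in (focal, *controls):
        if label not in condition_gene_sets:
            raise ValueError(f"unknown condition label {label!r}")
    focal_set = set(condition_gene_sets[focal])
    control_sets = [set(condition_gene_sets[c]) for c in controls]
    baseline = focal_set.intersection(*control_sets) if control_sets else focal_set
    union_controls = set().union(*control_sets) if control_sets else set()
    unique = focal_set - union_controls
    pairwise: dict[str, OverlapTest] = {}
    if population_size is not None:
        for c, cset in zip(controls, control_sets):
            pairwise[c] = OverlapTest.from_sets(focal_set, cset, population_size)
    return AccessibilityPartition(
        baseline_genes=frozenset(baseline),
        unique_genes=frozenset(unique),
        focal=focal,
        controls=tuple(controls),
        pairwise=pairwise,
    )


def affinity_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization then log2(x + 1).

    Rows are consensus intervals, columns samples; a zero-total sample is an
    error (library size undefined).
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative counts in affinity matrix input")
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        bad = counts.columns[totals == 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    cpm = mat / totals[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)
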