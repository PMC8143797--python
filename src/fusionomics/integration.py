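"""Cross-modality joins: DEGs x bound genes x unique open chromatin.

Each differentially expressed gene becomes one IntegrationRecord carrying
its expression significance (-log10 adjusted p, capped), the maximum ChIP
peak score among peaks assigned to it (0 if unbound), and whether it falls
in condition-unique accessible chromatin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import DEGRecord

__all__ = [
    "IntegrationRecord",
    "build_integration_table",
    "fraction_degs_bound",
    "fraction_degs_in_open",
    "significance_score_table",
]

PADJ_FLOOR = 1e-320  # upstream padj == 0 is an underflow; cap before -log10
NEGLOG10_CAP = 320.0


@dataclass(frozen=True)
class IntegrationRecord:
    gene_id: str
    deg_neglog10_padj: float
    peak_score: float
    bound: bool
    open_unique: bool


def _neglog10_padj(padj: float | None) -> float:
    if padj is None:
        return 0.0
    return min(NEGLOG10_CAP, -math.log10(max(padj, PADJ_FLOOR)))


def build_integration_table(
    deg_records: Sequence[DEGRecord],
    bound_gene_scores: Mapping[str, float],
    open_unique_genes: Iterable[str],
) -> list[IntegrationRecord]:
    """One record per DEG; modality flags joined by gene identifier.

    Genes absent from a modality take the neutral value (score 0, flag
    False).  The join is lossless on the DEG side.
    """
    seen: set[str] = set()
    for r in deg_records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene in DEG table: {r.gene_id}")
        seen.add(r.gene_id)
    open_set = set(open_unique_genes)
    records = []
    for r in deg_records:
        score = bound_gene_scores.get(r.gene_id)
        records.append(
            IntegrationRecord(
                gene_id=r.gene_id,
                deg_neglog10_padj=_neglog10_padj(r.padj),
                peak_score=score if score is not None else 0.0,
                bound=score is not None,
                open_unique=r.gene_id in open_set,
            )
        )
    return records


def fraction_degs_bound(records: Sequence[IntegrationRecord]) -> float:
    """Percentage of differentially expressed genes directly bound by the factor."""
    if not records:
        raise ValueError("no integration records")
    return 100.0 * sum(r.bound for r in records) / len(records)


def fraction_degs_in_open(
    deg_genes: Iterable[str], open_unique_genes: Iterable[str]
) -> float:
    """Percentage of DEGs lying within condition-unique open chromatin."""
    degs = set(deg_genes)
    if not degs:
        raise ValueError("empty DEG set")
    return 100.0 * len(degs & set(open_unique_genes)) / len(degs)


def significance_score_table(
    records: Sequence[IntegrationRecord],
    sig_threshold: float = 2.0,
    score_threshold: float = 50.0,
) -> list[dict]:
    """Two-axis export (-log10 padj vs peak score), sorted by peak score then
    significance; rows above both thresholds carry a top-right quadrant flag."""
    rows = [
        {
            "gene_id": r.gene_id,
            "neglog10_padj": r.deg_neglog10_padj,
            "peak_score": r.peak_score,
            "bound": r.bound,
            "top_right": r.deg_neglog10_padj > sig_threshold and r.peak_score > score_threshold,
        }
        for r in records
    ]
    rows.sort(key=lambda row: (row["peak_score"], row["neglog10_padj"], row["gene_id"]))
    return rows
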