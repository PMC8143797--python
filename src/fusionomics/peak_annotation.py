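"""Peak-to-TSS annotation and binding-geometry summaries.

Each peak is assigned to the gene with the nearest transcriptional start
site (TSS) and given a single feature category.  Distances are signed on
the gene's strand: negative means the peak lies upstream of the TSS.  The
three headline distance bins (0-1 kb, 1-3 kb, >=3 kb) summarise promoter-
proximal versus distal-intergenic/enhancer binding.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .core_io import GeneModel, GenomicInterval

__all__ = [
    "AnnotationScheme",
    "AnnotatedPeak",
    "CATEGORIES",
    "annotate_peak",
    "annotate_peaks",
    "category_distribution",
    "tss_profile",
    "peak_set_overlap_fraction",
    "assign_peaks_to_genes",
]

PROMOTER_1KB = "Promoter<=1kb"
PROMOTER_1_3KB = "Promoter1-3kb"
FIVE_UTR = "5'UTR"
EXON = "Exon"
INTRON = "Intron"
GENE_BODY = "GeneBody"
DOWNSTREAM = "Downstream<=3kb"
DISTAL = "DistalIntergenic"

CATEGORIES = (
    PROMOTER_1KB,
    PROMOTER_1_3KB,
    FIVE_UTR,
    EXON,
    INTRON,
    GENE_BODY,
    DOWNSTREAM,
    DISTAL,
)

DISTANCE_BINS = ("0-1kb", "1-3kb", ">=3kb")


@dataclass(frozen=True)
class AnnotationScheme:
    promoter_window: int = 1000
    promoter_far_window: int = 3000
    downstream_window: int = 3000
    profile_window: int = 3000
    profile_bins: int = 100
    distance_anchor: Literal["midpoint", "nearest-edge"] = "midpoint"

    def __post_init__(self) -> None:
        if not 0 < self.promoter_window <= self.promoter_far_window:
            raise ValueError("require 0 < promoter_window <= promoter_far_window")
        if self.profile_bins <= 0 or (2 * self.profile_window) % self.profile_bins:
            raise ValueError("profile window must tile evenly into profile_bins")


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: GenomicInterval
    nearest_gene: str | None
    tss_distance: float | None
    category: str


def _signed_distance(peak: GenomicInterval, gene: GeneModel, scheme: AnnotationScheme) -> float:
    """Distance from TSS to the peak anchor, signed on the gene strand."""
    tss = gene.tss
    if scheme.distance_anchor == "midpoint":
        anchor = peak.midpoint
    else:  # nearest-edge; 0 when the peak spans the TSS
        if peak.start <= tss < peak.end:
            anchor = float(tss)
        elif tss < peak.start:
            anchor = float(peak.start)
        else:
            anchor = float(peak.end - 1)
    d = anchor - tss
    return d if gene.strand == "+" else -d


def annotate_peak(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    scheme: AnnotationScheme = AnnotationScheme(),
) -> AnnotatedPeak:
    """Assign a peak to its nearest TSS and one feature category.

    Nearest gene minimises |signed distance|, ties broken by lexicographic
    gene_id.  Category precedence: promoter bins (both sides of the TSS),
    then gene-body features, then downstream window, then distal intergenic.
    Peaks on chromosomes absent from the annotation are DistalIntergenic
    with a null gene.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    same_chrom = [g for g in genes if g.chrom == peak.chrom]
    if not same_chrom:
        return AnnotatedPeak(peak, None, None, DISTAL)
    best = min(same_chrom, key=lambda g: (abs(_signed_distance(peak, g, scheme)), g.gene_id))
    d = _signed_distance(peak, best, scheme)
    category = _categorize(peak, best, d, scheme)
    return AnnotatedPeak(peak, best.gene_id, d, category)


def _categorize(
    peak: GenomicInterval, gene: GeneModel, d: float, scheme: AnnotationScheme
) -> str:
    if abs(d) <= scheme.promoter_window:
        return PROMOTER_1KB
    if abs(d) <= scheme.promoter_far_window:
        return PROMOTER_1_3KB
    anchor = peak.midpoint if scheme.distance_anchor == "midpoint" else None
    if anchor is None:  # nearest-edge: body membership judged by the midpoint
        anchor = peak.midpoint
    if gene.tx_start <= anchor < gene.tx_end:
        if not gene.exons:
            return GENE_BODY
        ordered = gene.exons if gene.strand == "+" else tuple(reversed(gene.exons))
        first_exon = ordered[0]
        if first_exon[0] <= anchor < first_exon[1]:
            return FIVE_UTR
        if any(s <= anchor < e for s, e in gene.exons):
            return EXON
        return INTRON
    # downstream of the gene body on the gene strand
    if gene.strand == "+":
        downstream = gene.tx_end <= anchor < gene.tx_end + scheme.downstream_window
    else:
        downstream = gene.tx_start - scheme.downstream_window <= anchor < gene.tx_start
    if downstream:
        return DOWNSTREAM
    return DISTAL


def annotate_peaks(
    peaks: Iterable[GenomicInterval],
    genes: Sequence[GeneModel],
    scheme: AnnotationScheme = AnnotationScheme(),
) -> list[AnnotatedPeak]:
    return [annotate_peak(p, genes, scheme) for p in peaks]


def category_distribution(
    annotated: Sequence[AnnotatedPeak],
) -> tuple[dict[str, float], dict[str, float]]:
    """Fractions per feature category and per TSS-distance bin.

    Both sets of fractions sum to 1; peaks with no annotated gene fall in
    the >=3kb distance bin.
    """
    if not annotated:
        raise ValueError("no annotated peaks")
    n = len(annotated)
    cats = Counter(a.category for a in annotated)
    bins: Counter = Counter()
    for a in annotated:
        if a.tss_distance is None or abs(a.tss_distance) >= 3000:
            bins[">=3kb"] += 1
        elif abs(a.tss_distance) <= 1000:
            bins["0-1kb"] += 1
        else:
            bins["1-3kb"] += 1
    return (
        {c: cats.get(c, 0) / n for c in CATEGORIES},
        {b: bins.get(b, 0) / n for b in DISTANCE_BINS},
    )


def tss_profile(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    scheme: AnnotationScheme = AnnotationScheme(),
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Binned peak occupancy around each TSS, oriented by gene strand.

    Returns (matrix, mean_profile, gene_ids).  Matrix entry [i, j] is the
    number of peak base pairs falling in bin j of the window
    [TSS - W, TSS + W) of gene i; for minus-strand genes the bins are
    reversed so upstream is always on the left.
    """
    W, nbins = scheme.profile_window, scheme.profile_bins
    bin_width = 2 * W // nbins
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append(p)
    for chrom_peaks in by_chrom.values():
        chrom_peaks.sort(key=lambda p: p.start)
    starts_by_chrom = {c: [p.start for p in ps] for c, ps in by_chrom.items()}

    matrix = np.zeros((len(genes), nbins))
    for gi, gene in enumerate(genes):
        win_start = gene.tss - W
        win_end = gene.tss + W
        chrom_peaks = by_chrom.get(gene.chrom, [])
        starts = starts_by_chrom.get(gene.chrom, [])
        # peaks starting before win_end can overlap; scan back for long peaks
        hi = bisect_left(starts, win_end)
        for p in chrom_peaks[:hi]:
            if p.end <= win_start:
                continue
            lo, hi_bp = max(p.start, win_start), min(p.end, win_end)
            for b in range(
                (lo - win_start) // bin_width, (hi_bp - 1 - win_start) // bin_width + 1
            ):
                bs = win_start + b * bin_width
                matrix[gi, b] += min(hi_bp, bs + bin_width) - max(lo, bs)
        if gene.strand == "-":
            matrix[gi] = matrix[gi, ::-1]
    return matrix, matrix.mean(axis=0) if len(genes) else np.zeros(nbins), [
        g.gene_id for g in genes
    ]


def peak_set_overlap_fraction(
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> float:
    """Percentage of peaks in A intersecting >=1 peak in B by >= min_overlap bp."""
    if not peaks_a:
        raise ValueError("peak set A is empty")
    b_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for p in peaks_b:
        b_by_chrom[p.chrom].append((p.start, p.end))
    for ivs in b_by_chrom.values():
        ivs.sort()
    hit = 0
    for a in peaks_a:
        ivs = b_by_chrom.get(a.chrom, [])
        # candidate B peaks start before a.end
        idx = bisect_right(ivs, (a.end - min_overlap, float("inf")))
        if any(
            min(a.end, e) - max(a.start, s) >= min_overlap for s, e in ivs[:idx]
        ):
            hit += 1
    return 100.0 * hit / len(peaks_a)


def assign_peaks_to_genes(
    annotated: Sequence[AnnotatedPeak],
) -> tuple[set[str], dict[str, list[AnnotatedPeak]], dict[str, float]]:
    """De-duplicated gene set, per-gene peak lists, and per-gene max score.

    Peaks without an annotated gene (absent chromosome) are excluded.
    """
    per_gene: dict[str, list[AnnotatedPeak]] = defaultdict(list)
    for a in annotated:
        if a.nearest_gene is not None:
            per_gene[a.nearest_gene].append(a)
    max_score = {g: max(a.peak.score for a in peaks) for g, peaks in per_gene.items()}
    return set(per_gene), dict(per_gene), max_score
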