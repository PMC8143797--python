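"""Nearest-TSS assignment, category geometry and occupancy profiles."""

import numpy as np
import pytest

from fusionomics.core_io import GeneModel, GenomicInterval
from fusionomics.peak_annotation import (
    DISTAL,
    DOWNSTREAM,
    GENE_BODY,
    PROMOTER_1KB,
    PROMOTER_1_3KB,
    AnnotationScheme,
    annotate_peak,
    annotate_peaks,
    assign_peaks_to_genes,
    category_distribution,
    peak_set_overlap_fraction,
    tss_profile,
)


def brute_force_annotate(peak, genes, scheme=AnnotationScheme()):
    """Independent oracle: plain all-pairs scan with its own arithmetic."""
    candidates = []
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        mid = (peak.start + peak.end) / 2
        d = (mid - g.tss) if g.strand == "+" else (g.tss - mid)
        candidates.append((abs(d), g.gene_id, d, g))
    if not candidates:
        return None, None
    _, gid, d, g = min(candidates)
    if abs(d) <= 1000:
        cat = PROMOTER_1KB
    elif abs(d) <= 3000:
        cat = PROMOTER_1_3KB
    else:
        mid = (peak.start + peak.end) / 2
        if g.tx_start <= mid < g.tx_end:
            cat = GENE_BODY
        elif g.strand == "+" and g.tx_end <= mid < g.tx_end + 3000:
            cat = DOWNSTREAM
        elif g.strand == "-" and g.tx_start - 3000 <= mid < g.tx_start:
            cat = DOWNSTREAM
        else:
            cat = DISTAL
    return gid, cat


class TestAnnotatePeak:
    def test_promoter_upstream_of_plus_gene(self, genes_two):
        # midpoint 925, TSS 1000: 75 bp upstream
        a = annotate_peak(GenomicInterval("chr1", 900, 950), genes_two)
        assert a.nearest_gene == "gA"
        assert a.tss_distance == -75
        assert a.category == PROMOTER_1KB

    def test_midpoint_on_tss(self, genes_two):
        a = annotate_peak(GenomicInterval("chr1", 950, 1050), genes_two)
        assert a.tss_distance == 0 and a.category == PROMOTER_1KB

    def test_distal_beyond_all_features(self, genes_two):
        # midpoint 9500: >3 kb from both TSSs, outside bodies and
        # downstream windows
        a = annotate_peak(GenomicInterval("chr1", 9450, 9550), genes_two)
        assert a.category == DISTAL

    def test_downstream_window(self, genes_two):
        # midpoint 4500 is 1500 bp past gA's body end
        a = annotate_peak(GenomicInterval("chr1", 4450, 4550), genes_two)
        assert a.category == DOWNSTREAM

    def test_minus_strand_sign_convention(self, genes_two):
        # gB TSS = 21999; peak midpoint at 22499 is 500 bp UPSTREAM on - strand
        a = annotate_peak(GenomicInterval("chr1", 22449, 22549), genes_two)
        assert a.nearest_gene == "gB"
        assert a.tss_distance == -500

    def test_missing_chromosome_distal_null_gene(self, genes_two):
        a = annotate_peak(GenomicInterval("chrX", 0, 100), genes_two)
        assert a.nearest_gene is None and a.category == DISTAL

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            annotate_peak(GenomicInterval("chr1", 0, 100), [])

    def test_tie_broken_by_gene_id(self):
        genes = [
            GeneModel("gB", "chr1", "+", 2000, 3000),
            GeneModel("gA", "chr1", "+", 0, 1000),
        ]
        # midpoint 1000: equidistant (1000) from TSS 0 and TSS 2000
        a = annotate_peak(GenomicInterval("chr1", 950, 1050), genes)
        assert a.nearest_gene == "gA"

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(17)
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 500_000))
            genes.append(
                GeneModel(f"g{i:03d}", f"chr{1 + i % 2}",
                          "+" if rng.random() < 0.5 else "-",
                          start, start + int(rng.integers(500, 5000)))
            )
        for _ in range(300):
            s = int(rng.integers(0, 500_000))
            peak = GenomicInterval(f"chr{int(rng.integers(1, 3))}", s, s + 200)
            a = annotate_peak(peak, genes)
            gid, cat = brute_force_annotate(peak, genes)
            assert a.nearest_gene == gid
            assert a.category == cat


class TestCategoryDistribution:
    def test_all_promoter(self, genes_two):
        peaks = [GenomicInterval("chr1", 950, 1050)] * 4
        cats, bins = category_distribution(annotate_peaks(peaks, genes_two))
        assert cats[PROMOTER_1KB] == 1.0 and bins["0-1kb"] == 1.0

    def test_half_half(self, genes_two):
        peaks = [GenomicInterval("chr1", 950, 1050)] * 2 + [
            GenomicInterval("chr1", 10_000, 10_200)
        ] * 2
        cats, bins = category_distribution(annotate_peaks(peaks, genes_two))
        assert cats[PROMOTER_1KB] == 0.5 and cats[DISTAL] == 0.5
        assert sum(cats.values()) == pytest.approx(1.0)
        assert sum(bins.values()) == pytest.approx(1.0)

    def test_symmetry_under_strand_flip_and_reflection(self):
        rng = np.random.default_rng(23)
        L = 200_000
        genes = [
            GeneModel(f"g{i}", "chr1", "+" if i % 2 else "-",
                      int(s := rng.integers(3000, L - 8000)), int(s) + 2000)
            for i in range(20)
        ]
        peaks = []
        for _ in range(200):
            s = int(rng.integers(0, L - 300))
            peaks.append(GenomicInterval("chr1", s, s + 200))
        cats, _ = category_distribution(annotate_peaks(peaks, genes))
        flipped = [
            GeneModel(g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                      L - g.tx_end, L - g.tx_start)
            for g in genes
        ]
        reflected = [GenomicInterval("chr1", L - p.end, L - p.start) for p in peaks]
        cats2, _ = category_distribution(annotate_peaks(reflected, flipped))
        for c in cats:
            assert cats[c] == pytest.approx(cats2[c])


class TestTssProfile:
    def test_peak_covering_plus_tss_fills_central_bins(self, genes_two):
        # gA TSS 1000; peak [970, 1030) with W=3000, 100 bins of 60 bp
        matrix, mean, ids = tss_profile(
            [GenomicInterval("chr1", 970, 1030)], [genes_two[0]]
        )
        nz = np.nonzero(matrix[0])[0]
        assert list(nz) == [49, 50]
        assert matrix[0].sum() == 60

    def test_no_peaks_zero_matrix(self, genes_two):
        matrix, mean, _ = tss_profile([], genes_two)
        assert matrix.sum() == 0 and mean.sum() == 0

    def test_minus_strand_orientation_flip(self, genes_two):
        gB = genes_two[1]  # TSS 21999, strand -
        # 600 bp upstream on - strand = higher coordinate
        peak = GenomicInterval("chr1", 22550, 22650)
        matrix, _, _ = tss_profile([peak], [gB])
        nz = np.nonzero(matrix[0])[0]
        assert (nz < 50).all()  # upstream mass appears on the left half

    def test_mass_conserved_across_binnings(self, genes_two):
        peaks = [GenomicInterval("chr1", 500, 2100), GenomicInterval("chr1", 2500, 2700)]
        totals = []
        for bins in (50, 100, 200):
            m, _, _ = tss_profile(peaks, genes_two, AnnotationScheme(profile_bins=bins))
            totals.append(m.sum())
        assert totals[0] == totals[1] == totals[2]

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError):
            AnnotationScheme(profile_window=3000, profile_bins=7)


class TestPeakSetOverlap:
    def test_basic_overlap(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 50, 150)]
        assert peak_set_overlap_fraction(a, b) == 100.0

    def test_disjoint(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 200, 300)]
        assert peak_set_overlap_fraction(a, b) == 0.0

    def test_planted_fraction(self):
        rng = np.random.default_rng(4)
        a, b = [], []
        for i in range(100):
            s = 1000 * i
            a.append(GenomicInterval("chr1", s, s + 200))
            if i < 69:
                b.append(GenomicInterval("chr1", s + 100, s + 300))
        assert peak_set_overlap_fraction(a, b) == 69.0

    def test_min_overlap_threshold(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 99, 200)]
        assert peak_set_overlap_fraction(a, b, min_overlap=1) == 100.0
        assert peak_set_overlap_fraction(a, b, min_overlap=2) == 0.0

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            peak_set_overlap_fraction([], [GenomicInterval("chr1", 0, 10)])


class TestAssignPeaksToGenes:
    def test_multiple_peaks_one_gene(self, genes_two):
        peaks = [
            GenomicInterval("chr1", 900, 1000, score=10),
            GenomicInterval("chr1", 1000, 1100, score=30),
            GenomicInterval("chr1", 1100, 1200, score=20),
        ]
        gene_set, per_gene, max_score = assign_peaks_to_genes(
            annotate_peaks(peaks, genes_two)
        )
        assert gene_set == {"gA"}
        assert len(per_gene["gA"]) == 3
        assert max_score["gA"] == 30

    def test_no_peaks(self):
        gene_set, per_gene, max_score = assign_peaks_to_genes([])
        assert gene_set == set() and per_gene == {} and max_score == {}

    def test_null_gene_peaks_excluded(self, genes_two):
        annotated = annotate_peaks([GenomicInterval("chrZ", 0, 10)], genes_two)
        gene_set, _, _ = assign_peaks_to_genes(annotated)
        assert gene_set == set()
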