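"""Seeded synthetic-data generators for every pipeline stage.

Each generator plants a known structure — shared transcriptional core plus
fusion-unique genes, promoter/distal peak placement with motif instances,
baseline vs unique accessible genes, enriched shared BioID preys, screen
hit genes — and returns both the data (in the exact formats ``core_io``
reads) and the ground truth, so planted-parameter recovery is testable
without any external download.

Default design parameters encode the study conditions the pipeline is
meant to reproduce: 70%/9% transcriptome overlaps with a 29% fusion-unique
remainder (one panel) and 53%/0.2% (the other), 58%/61% and 38%/51% motif
plant rates, a 68-prey interactome whose prioritization cascade retains
55/34 -> 49/31 -> 47/28 -> 27 -> 18 preys, 13%/15% bound-DEG fractions,
71%/74% knockdown-DEG-in-unique-open fractions, and a 15-gene screen with
three 5/5-effective hits.  Sizes are scaled to desk scale; see the methods
documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import DEGRecord, GeneModel, GenomicInterval, GrowthCurve, PreyObservation
from .motif_scan import PWM

__all__ = [
    "GenomeDesign",
    "DEGDesign",
    "PeakDesign",
    "ATACDesign",
    "BioIDDesign",
    "IntegrationDesign",
    "ScreenDesign",
    "SimConfig",
    "TEAD_PWM",
    "HIPPO_GENES",
    "make_toy_genome",
    "simulate_deg_tables",
    "simulate_peaks",
    "simulate_atac_gene_sets",
    "simulate_bioid",
    "simulate_integration",
    "simulate_screen",
]

# Strong MCAT-like matrix (TEAD consensus ACATTCCA) used for motif planting.
TEAD_PWM = PWM(
    name="TEAD_MCAT",
    counts=tuple(
        tuple(97.0 if b == base else 1.0 for b in "ACGT") for base in "ACATTCCA"
    ),
)

# Core Hippo-pathway kinases/adaptors, for the cascade's subtraction step.
HIPPO_GENES = (
    "LATS1", "LATS2", "STK3", "STK4", "SAV1", "MOB1A", "MOB1B", "NF2",
    "TEAD1", "TEAD2", "TEAD3", "TEAD4", "AMOTL1", "AMOTL2", "YWHAE",
)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent deterministic stream per sub-generator."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class GenomeDesign:
    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 600_000), ("chr2", 400_000))
    n_genes: int = 100
    gene_length: int = 2000
    min_spacing: int = 6000  # >= 2 x promoter_far_window between bodies


@dataclass(frozen=True)
class DEGDesign:
    fusion_size: int = 1000
    activator_size: int = 2000
    partner_size: int = 400
    activator_overlap: float = 0.70
    partner_overlap: float = 0.09
    triple_overlap: float = 0.08
    n_genes: int = 6000
    n_population: int = 5000
    noise_rate: float = 0.0
    effect_log2fc: float = 2.0
    effect_sd: float = 0.5
    replicates: int = 3


@dataclass(frozen=True)
class PeakDesign:
    n_peaks: int = 500
    peak_width: int = 200
    promoter_fraction: float = 0.3
    motif_plant_rate: float = 0.61
    n_replicates: int = 3
    replicate_jitter: int = 0


@dataclass(frozen=True)
class ATACDesign:
    baseline_size: int = 2000
    unique_sizes: tuple[tuple[str, int], ...] = (
        ("fusion", 315),
        ("EV", 30),
        ("FL1", 66),
        ("FL2", 50),
    )
    noise_rate: float = 0.005


@dataclass(frozen=True)
class BioIDDesign:
    """Prey-category sizes chosen so the cascade retains, per step,
    64/38 -> 55/34 -> 49/31 -> 47/28 -> 27 -> 18 preys (union 68)."""

    n_shared_strong: int = 18
    n_shared_weak: int = 9
    n_tc_only_increased: int = 20
    n_yt_only_increased: int = 1
    n_tc_unchanged: int = 2
    n_yt_unchanged: int = 3
    n_hippo_shared: int = 3
    n_hippo_tc_only: int = 3
    n_decreased_tc: int = 9
    n_decreased_both: int = 4  # of the decreased, also seen (decreased) with YT
    n_background: int = 25
    strong_mean: float = 45.0
    weak_max_avg: float = 12.0
    replicates: int = 2


@dataclass(frozen=True)
class IntegrationDesign:
    bound_fraction: float = 0.13
    n_extra_bound: int = 200
    kd_deg_size: int = 400
    kd_open_fractions: tuple[tuple[str, float], ...] = (
        ("shYEATS2", 0.71),
        ("shZZZ3", 0.74),
    )
    open_unique_size: int = 2500


@dataclass(frozen=True)
class ScreenDesign:
    n_genes: int = 15
    shrnas_per_gene: int = 5
    replicates: int = 3
    full_hit_genes: int = 3  # all 5 shRNAs effective
    partial_hits: tuple[tuple[int, int], ...] = ((3, 3), (3, 1))  # (n genes, n effective)
    control_day10_fc: float = 5.0
    effect_ratio: float = 0.4  # day-10 FC of an effective shRNA vs control
    log_sd: float = 0.05
    days: tuple[int, ...] = (0, 2, 4, 6, 8, 10)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome: GenomeDesign = GenomeDesign()
    deg: DEGDesign = DEGDesign()
    peaks: PeakDesign = PeakDesign()
    atac: ATACDesign = ATACDesign()
    bioid: BioIDDesign = BioIDDesign()
    integration: IntegrationDesign = IntegrationDesign()
    screen: ScreenDesign = ScreenDesign()


# ---------------------------------------------------------------------------
# Genome


def make_toy_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random contigs with evenly tiled, alternating-strand, non-overlapping
    genes separated by at least the design spacing."""
    g = config.genome
    rng = _rng(config.seed, 0)
    total_len = sum(l for _, l in g.chrom_lengths)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_idx = 0
    for chrom, length in g.chrom_lengths:
        genome[chrom] = "".join(rng.choice(list("ACGT"), size=length))
        n_here = round(g.n_genes * length / total_len)
        if chrom == g.chrom_lengths[-1][0]:
            n_here = g.n_genes - gene_idx  # absorb rounding in the last contig
        stride = length // max(n_here, 1)
        if stride < g.gene_length + g.min_spacing:
            raise ValueError(
                f"{n_here} genes of {g.gene_length} bp with {g.min_spacing} bp "
                f"spacing do not fit contig {chrom} ({length} bp)"
            )
        for i in range(n_here):
            start = i * stride + g.min_spacing // 2
            genes.append(
                GeneModel(
                    gene_id=f"g{gene_idx:04d}",
                    chrom=chrom,
                    strand="+" if gene_idx % 2 == 0 else "-",
                    tx_start=start,
                    tx_end=start + g.gene_length,
                )
            )
            gene_idx += 1
    return genome, genes


# ---------------------------------------------------------------------------
# Expression


@dataclass(frozen=True)
class DEGTruth:
    fusion: frozenset
    activator: frozenset
    partner: frozenset
    population: frozenset


def _draw_padj(rng: np.random.Generator, significant: bool) -> float:
    if significant:
        return float(10 ** rng.uniform(-8, np.log10(0.049)))
    return float(rng.uniform(0.051, 1.0))


def simulate_deg_tables(
    config: SimConfig,
) -> tuple[dict[str, list[DEGRecord]], pd.DataFrame, DEGTruth]:
    """Per-condition DEG tables plus a count matrix consistent with the
    population rule (genes with mean count >= 5 across all samples).

    The fusion set shares ``activator_overlap`` of its genes with the
    activator set and ``partner_overlap`` with the partner set
    (``triple_overlap`` in all three); remaining fusion genes are unique.
    """
    d = config.deg
    rng = _rng(config.seed, 1)
    n_shared_act = round(d.activator_overlap * d.fusion_size)
    n_shared_par = round(d.partner_overlap * d.fusion_size)
    n_triple = round(d.triple_overlap * d.fusion_size)
    if n_triple > min(n_shared_act, n_shared_par):
        raise ValueError(
            f"triple overlap {n_triple} exceeds a pairwise overlap "
            f"({n_shared_act} with activator, {n_shared_par} with partner)"
        )
    n_unique = d.fusion_size - n_shared_act - n_shared_par + n_triple
    if n_unique < 0:
        raise ValueError("overlap fractions exceed the fusion set size")
    if d.activator_size < n_shared_act or d.partner_size < n_shared_par:
        raise ValueError("control set sizes smaller than their planted overlaps")

    gene_ids = [f"g{i:05d}" for i in range(d.n_genes)]
    pool = list(rng.permutation(gene_ids[: d.n_population]))
    take = lambda n: [pool.pop() for _ in range(n)]

    triple = take(n_triple)
    act_only_shared = take(n_shared_act - n_triple)
    par_only_shared = take(n_shared_par - n_triple)
    fusion_unique = take(n_unique)
    act_rest = take(d.activator_size - n_shared_act)
    par_rest = take(d.partner_size - n_shared_par)

    fusion = set(triple + act_only_shared + par_only_shared + fusion_unique)
    activator = set(triple + act_only_shared + act_rest)
    partner = set(triple + par_only_shared + par_rest)

    tables: dict[str, list[DEGRecord]] = {}
    for label, members in [("fusion", fusion), ("activator", activator), ("partner", partner)]:
        records = []
        for gid in gene_ids:
            sig = gid in members
            if d.noise_rate > 0 and rng.random() < d.noise_rate:
                sig = not sig
            lfc = float(rng.normal(0, 0.3))
            if sig:
                lfc = float(rng.choice([-1, 1]) * rng.normal(d.effect_log2fc, d.effect_sd))
            padj = _draw_padj(rng, sig)
            records.append(DEGRecord(gid, lfc, min(1.0, padj), padj))
        tables[label] = records

    # count matrix: population genes well above threshold, the rest far below
    base_mean = np.empty(d.n_genes)
    base_mean[: d.n_population] = np.exp(rng.uniform(np.log(10), np.log(1000), d.n_population))
    base_mean[d.n_population :] = rng.uniform(0.0, 1.5, d.n_genes - d.n_population)
    conditions = ["EV", "fusion", "activator", "partner"]
    effect = {c: {} for c in conditions}
    for label, members in [("fusion", fusion), ("activator", activator), ("partner", partner)]:
        for r in tables[label]:
            if r.gene_id in members:
                effect[label][r.gene_id] = 2.0 ** r.log2fc
    cols, data = [], []
    for cond in conditions:
        mult = np.array([effect[cond].get(g, 1.0) if cond != "EV" else 1.0 for g in gene_ids])
        for rep in range(d.replicates):
            cols.append(f"{cond}_{rep + 1}")
            data.append(rng.poisson(base_mean * mult))
    counts = pd.DataFrame(np.array(data).T, index=gene_ids, columns=cols)
    truth = DEGTruth(
        frozenset(fusion),
        frozenset(activator),
        frozenset(partner),
        frozenset(gene_ids[: d.n_population]),
    )
    return tables, counts, truth


# ---------------------------------------------------------------------------
# Peaks and motifs


@dataclass(frozen=True)
class PeakTruth:
    promoter_flags: tuple[bool, ...]
    motif_flags: tuple[bool, ...]


def simulate_peaks(
    config: SimConfig,
    genome: dict[str, str],
    genes: list[GeneModel],
    pwm: PWM = TEAD_PWM,
) -> tuple[list[GenomicInterval], dict[str, list[GenomicInterval]], dict[str, str], PeakTruth]:
    """Place peaks in promoter windows or distal intergenic space and plant
    motif consensus words into a chosen fraction of them.

    Returns (peaks, per-replicate jittered peak sets, genome with planted
    motifs, truth).  The returned genome is a modified copy.
    """
    p = config.peaks
    rng = _rng(config.seed, 2)
    chrom_len = {c: len(s) for c, s in genome.items()}
    seqs = {c: list(s) for c, s in genome.items()}
    half = p.peak_width // 2

    # distal space: midpoints >= 3 kb from every TSS and outside bodies
    gaps: list[tuple[str, int, int]] = []
    for chrom in chrom_len:
        spans = sorted(
            (g.tx_start - 3000, g.tx_end + 3000) for g in genes if g.chrom == chrom
        )
        prev = 0
        for s, e in spans:
            if s - prev >= p.peak_width + 200:
                gaps.append((chrom, prev + half + 1, s - half - 1))
            prev = max(prev, e)
        if chrom_len[chrom] - prev >= p.peak_width + 200:
            gaps.append((chrom, prev + half + 1, chrom_len[chrom] - half - 1))
    if not gaps:
        raise ValueError("no intergenic space to place distal peaks")

    peaks: list[GenomicInterval] = []
    promoter_flags: list[bool] = []
    motif_flags: list[bool] = []
    consensus = pwm.consensus()
    occupied: dict[str, list[int]] = {c: [] for c in chrom_len}
    for i in range(p.n_peaks):
        promoter = rng.random() < p.promoter_fraction
        # rejection-sample a midpoint so peaks never overlap one another
        # (a planted word must belong to exactly one peak)
        for _ in range(500):
            if promoter:
                gene = genes[rng.integers(len(genes))]
                offset = int(rng.integers(-800 + half, 800 - half + 1))
                mid = gene.tss + offset
                chrom = gene.chrom
            else:
                chrom, lo, hi = gaps[rng.integers(len(gaps))]
                mid = int(rng.integers(lo, hi + 1))
            if all(abs(mid - m) >= p.peak_width for m in occupied[chrom]):
                break
        else:
            raise ValueError("peak placement impossible: no non-overlapping position found")
        occupied[chrom].append(mid)
        start, end = mid - half, mid + half
        score = float(np.round(rng.uniform(10, 100), 2))
        peaks.append(GenomicInterval(chrom, start, end, name=f"pk{i:04d}", score=score))
        promoter_flags.append(promoter)
        planted = rng.random() < p.motif_plant_rate
        motif_flags.append(planted)
        if planted:
            at = mid - len(consensus) // 2
            seqs[chrom][at : at + len(consensus)] = list(consensus)

    replicates: dict[str, list[GenomicInterval]] = {}
    for rep in range(p.n_replicates):
        shifted = []
        for pk in peaks:
            shift = int(rng.normal(0, p.replicate_jitter)) if p.replicate_jitter else 0
            start = max(0, pk.start + shift)
            shifted.append(
                GenomicInterval(pk.chrom, start, start + pk.length, name=pk.name, score=pk.score)
            )
        replicates[f"rep{rep + 1}"] = shifted

    planted_genome = {c: "".join(s) for c, s in seqs.items()}
    return peaks, replicates, planted_genome, PeakTruth(tuple(promoter_flags), tuple(motif_flags))


# ---------------------------------------------------------------------------
# ATAC gene sets


@dataclass(frozen=True)
class ATACTruth:
    baseline: frozenset
    unique: dict[str, frozenset]


def simulate_atac_gene_sets(
    config: SimConfig,
) -> tuple[dict[str, set], ATACTruth]:
    """Per-condition accessible-gene sets with a planted shared baseline and
    per-condition unique genes; membership noise flips at ``noise_rate``."""
    a = config.atac
    rng = _rng(config.seed, 3)
    labels = [label for label, _ in a.unique_sizes]
    idx = 0

    def fresh(n: int) -> set:
        nonlocal idx
        out = {f"atac_g{idx + i:05d}" for i in range(n)}
        idx += n
        return out

    baseline = fresh(a.baseline_size)
    unique = {label: fresh(n) for label, n in a.unique_sizes}
    universe = baseline | set().union(*unique.values())
    sets: dict[str, set] = {}
    for label in labels:
        members = baseline | unique[label]
        if a.noise_rate > 0:
            flip = {g for g in universe if rng.random() < a.noise_rate}
            members = members ^ flip
        sets[label] = members
    return sets, ATACTruth(frozenset(baseline), {l: frozenset(u) for l, u in unique.items()})


# ---------------------------------------------------------------------------
# BioID


@dataclass(frozen=True)
class BioIDTruth:
    shared_strong: frozenset
    shared_weak: frozenset
    hippo_preys: frozenset
    expected_steps: dict[str, tuple[int, ...]]
    expected_intersection: int
    expected_final: int


def _nb_counts(rng: np.random.Generator, mean: float, n: int, floor: int = 0) -> tuple[int, ...]:
    # negative-binomial-like: gamma-mixed Poisson, dispersion ~ mean/5
    lam = rng.gamma(shape=5.0, scale=mean / 5.0, size=n)
    return tuple(int(max(floor, c)) for c in rng.poisson(lam))


def simulate_bioid(config: SimConfig) -> tuple[dict[str, list[PreyObservation]], BioIDTruth]:
    """Prey tables for the two fusion baits and their full-length controls.

    Categories are constructed so every cascade filter acts on a known
    subset; with the default sizes the per-step counts are
    64/38 -> 55/34 -> 49/31 -> 47/28 -> 27 -> 18 and the union of
    high-confidence preys across baits is 68.
    """
    b = config.bioid
    rng = _rng(config.seed, 4)
    tables: dict[str, list[PreyObservation]] = {
        "TAZ-CAMTA1": [], "YAP-TFE3": [], "TAZ": [], "YAP": []
    }

    def add(bait: str, prey: str, counts: tuple[int, ...], abundance: float,
            probability: float = 0.99, bfdr: float = 0.005) -> None:
        tables[bait].append(
            PreyObservation(bait, prey, counts, round(abundance, 3), probability, bfdr)
        )

    def strong_counts() -> tuple[int, ...]:
        c = _nb_counts(rng, b.strong_mean, b.replicates)
        if max(c) < 10:  # detection guaranteed for planted enriched preys
            c = tuple(x + 10 for x in c)
        return c

    names = iter(f"PREY{i:03d}" for i in range(1000))
    shared_strong = [next(names) for _ in range(b.n_shared_strong)]
    shared_weak = [next(names) for _ in range(b.n_shared_weak)]
    tc_only = [next(names) for _ in range(b.n_tc_only_increased)]
    yt_only = [next(names) for _ in range(b.n_yt_only_increased)]
    tc_unch = [next(names) for _ in range(b.n_tc_unchanged)]
    yt_unch = [next(names) for _ in range(b.n_yt_unchanged)]
    hippo_pool = list(HIPPO_GENES)
    hippo_shared = hippo_pool[: b.n_hippo_shared]
    hippo_tc = hippo_pool[b.n_hippo_shared : b.n_hippo_shared + b.n_hippo_tc_only]
    decreased = [next(names) for _ in range(b.n_decreased_tc)]

    # increased-for-both, absent from the full-length dotplots
    for prey in shared_strong:
        add("TAZ-CAMTA1", prey, strong_counts(), rng.uniform(3, 8))
        add("YAP-TFE3", prey, strong_counts(), rng.uniform(3, 8))
    for prey in shared_weak:
        # detectable (one replicate >= 10) yet in the lowest count/abundance
        # bin with BFDR above 5%: eliminated only at the final step
        for bait in ("TAZ-CAMTA1", "YAP-TFE3"):
            second = int(rng.integers(0, int(2 * b.weak_max_avg - 10) + 1))
            add(bait, prey, (10, second), rng.uniform(0.2, 0.9), bfdr=float(rng.uniform(0.06, 0.3)))
    for prey in tc_only:
        add("TAZ-CAMTA1", prey, strong_counts(), rng.uniform(2, 6))
    for prey in yt_only:
        add("YAP-TFE3", prey, strong_counts(), rng.uniform(2, 6))
    # unchanged: identical average counts fusion vs full-length
    for prey in tc_unch:
        c = strong_counts()
        add("TAZ-CAMTA1", prey, c, rng.uniform(1, 4))
        add("TAZ", prey, c, rng.uniform(1, 4))
    for prey in yt_unch:
        c = strong_counts()
        add("YAP-TFE3", prey, c, rng.uniform(1, 4))
        add("YAP", prey, c, rng.uniform(1, 4))
    # Hippo components: increased interactions, removed by list subtraction
    for prey in hippo_shared:
        add("TAZ-CAMTA1", prey, strong_counts(), rng.uniform(2, 6))
        add("YAP-TFE3", prey, strong_counts(), rng.uniform(2, 6))
    for prey in hippo_tc:
        add("TAZ-CAMTA1", prey, strong_counts(), rng.uniform(2, 6))
    # decreased vs full-length (Crumbs-complex-like): low with the fusion,
    # high with the full-length control
    for i, prey in enumerate(decreased):
        add("TAZ-CAMTA1", prey, (int(rng.integers(10, 14)), int(rng.integers(0, 6))),
            rng.uniform(0.5, 2))
        add("TAZ", prey, strong_counts(), rng.uniform(3, 8))
        if i < b.n_decreased_both:
            add("YAP-TFE3", prey, (int(rng.integers(10, 14)), int(rng.integers(0, 6))),
                rng.uniform(0.5, 2))
            add("YAP", prey, strong_counts(), rng.uniform(3, 8))
    # background preys failing detection or probability filters
    for i in range(b.n_background):
        prey = next(names)
        bait = ("TAZ-CAMTA1", "YAP-TFE3", "TAZ", "YAP")[i % 4]
        if i % 2 == 0:
            add(bait, prey, (int(rng.integers(0, 9)), int(rng.integers(0, 9))),
                rng.uniform(0.1, 1), probability=0.99)
        else:
            add(bait, prey, strong_counts(), rng.uniform(1, 4),
                probability=float(rng.uniform(0.3, 0.94)))

    n_inter = b.n_shared_strong + b.n_shared_weak
    truth = BioIDTruth(
        shared_strong=frozenset(shared_strong),
        shared_weak=frozenset(shared_weak),
        hippo_preys=frozenset(hippo_shared + hippo_tc),
        expected_steps={
            "TAZ-CAMTA1": (
                n_inter + b.n_tc_only_increased + b.n_tc_unchanged
                + b.n_hippo_shared + b.n_hippo_tc_only + b.n_decreased_tc,
                n_inter + b.n_tc_only_increased + b.n_tc_unchanged
                + b.n_hippo_shared + b.n_hippo_tc_only,
                n_inter + b.n_tc_only_increased + b.n_tc_unchanged,
                n_inter + b.n_tc_only_increased,
            ),
            "YAP-TFE3": (
                n_inter + b.n_yt_only_increased + b.n_yt_unchanged
                + b.n_hippo_shared + b.n_decreased_both,
                n_inter + b.n_yt_only_increased + b.n_yt_unchanged + b.n_hippo_shared,
                n_inter + b.n_yt_only_increased + b.n_yt_unchanged,
                n_inter + b.n_yt_only_increased,
            ),
        },
        expected_intersection=n_inter,
        expected_final=b.n_shared_strong,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Integration joins


@dataclass(frozen=True)
class IntegrationTruth:
    bound_genes: frozenset
    open_unique: frozenset
    kd_deg_sets: dict[str, frozenset]
    planted_bound_fraction: float
    planted_open_fractions: dict[str, float]


def simulate_integration(
    config: SimConfig, deg_genes: frozenset | set
) -> tuple[dict[str, float], frozenset, dict[str, frozenset], IntegrationTruth]:
    """Construct bound-gene scores and unique-open-chromatin sets so the
    planted join fractions are exact (noise-free construction).

    Returns (bound_gene_scores, open_unique_genes, knockdown DEG sets, truth).
    """
    it = config.integration
    rng = _rng(config.seed, 5)
    degs = sorted(deg_genes)
    n_bound = round(it.bound_fraction * len(degs))
    bound = set(rng.choice(degs, size=n_bound, replace=False))
    bound |= {f"bound_extra{i:04d}" for i in range(it.n_extra_bound)}
    scores = {g: float(np.round(rng.uniform(20, 100), 2)) for g in sorted(bound)}

    open_unique = {f"open_g{i:05d}" for i in range(it.open_unique_size)}
    kd_sets: dict[str, frozenset] = {}
    open_list = sorted(open_unique)
    for kd, frac in it.kd_open_fractions:
        n_in = round(frac * it.kd_deg_size)
        inside = list(rng.choice(open_list, size=n_in, replace=False))
        outside = [f"{kd}_deg{i:04d}" for i in range(it.kd_deg_size - n_in)]
        kd_sets[kd] = frozenset(inside + outside)
    truth = IntegrationTruth(
        bound_genes=frozenset(bound),
        open_unique=frozenset(open_unique),
        kd_deg_sets=kd_sets,
        planted_bound_fraction=100.0 * n_bound / len(degs),
        planted_open_fractions={
            kd: 100.0 * round(frac * it.kd_deg_size) / it.kd_deg_size
            for kd, frac in it.kd_open_fractions
        },
    )
    return scores, frozenset(open_unique), kd_sets, truth


# ---------------------------------------------------------------------------
# Screen


@dataclass(frozen=True)
class ScreenTruth:
    effective: dict[str, int]  # gene -> number of effective shRNAs
    full_hits: frozenset


def simulate_screen(config: SimConfig) -> tuple[list[GrowthCurve], ScreenTruth]:
    """Log-normal multiplicative growth curves for a 15-gene, 5-shRNA screen
    plus shEV/shNT controls; hit genes' shRNAs grow at a reduced rate."""
    s = config.screen
    rng = _rng(config.seed, 6)
    r_control = np.log(s.control_day10_fc) / 10.0
    r_effect = r_control + np.log(s.effect_ratio) / 10.0

    effective: dict[str, int] = {}
    gi = 0
    for _ in range(s.full_hit_genes):
        effective[f"GENE{gi:02d}"] = s.shrnas_per_gene
        gi += 1
    for n_genes, n_eff in s.partial_hits:
        for _ in range(n_genes):
            effective[f"GENE{gi:02d}"] = n_eff
            gi += 1
    while gi < s.n_genes:
        effective[f"GENE{gi:02d}"] = 0
        gi += 1

    curves: list[GrowthCurve] = []

    def make_curve(construct: str, gene: str, rep: int, rate: float) -> GrowthCurve:
        a0 = 0.2 * float(np.exp(rng.normal(0, s.log_sd)))
        readings = tuple(
            (day, round(a0 * float(np.exp(rate * day + rng.normal(0, s.log_sd))), 6))
            for day in s.days
        )
        return GrowthCurve("SW872", construct, gene, rep, readings)

    for ctrl in ("shEV", "shNT"):
        for rep in range(1, s.replicates + 1):
            curves.append(make_curve(ctrl, "control", rep, r_control))
    for gene, n_eff in effective.items():
        for sh in range(1, s.shrnas_per_gene + 1):
            rate = r_effect if sh <= n_eff else r_control
            for rep in range(1, s.replicates + 1):
                curves.append(make_curve(f"sh{gene}#{sh}", gene, rep, rate))
    truth = ScreenTruth(
        effective=effective,
        full_hits=frozenset(g for g, n in effective.items() if n == s.shrnas_per_gene),
    )
    return curves, truth


# ---------------------------------------------------------------------------
# Presets


def preset(name: str, seed: int = 0) -> SimConfig:
    """Named study-condition presets for each figure-style design."""
    base = SimConfig(seed=seed)
    if name in {"fig3", "fig4", "fig5", "fig6", "fig7", "fig8", "full"}:
        return base
    if name == "fig3_yt":
        # SW872 YAP-TFE3 panel: 53% / 0.2% overlaps; the partner (TFE3)
        # program is near-empty, so its overlap is a near-null association
        return replace(
            base,
            deg=replace(
                base.deg,
                activator_overlap=0.53,
                partner_overlap=0.002,
                partner_size=10,
                triple_overlap=0.0,
            ),
        )
    raise ValueError(f"unknown preset {name!r}")
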