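"""PWM scanning with exact score p-values and motif-proportion summaries.

Scores are position-weight-matrix log-odds in bits against a 0-order
background.  The p-value of a score s is the exact probability that a
random background word of the motif's width scores >= s, obtained by
dynamic programming over the integerized per-position score distribution
(resolution ``epsilon`` bits, default 1/1000); the integerization error is
bounded by w * epsilon in score units.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

__all__ = [
    "PWM",
    "MotifHit",
    "pwm_log_odds",
    "score_distribution",
    "motif_score_pvalue",
    "scan_sequence",
    "peak_motif_proportion",
    "estimate_background",
    "motif_set_association",
    "read_meme",
    "read_pfm",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class PWM:
    """A position weight matrix over {A, C, G, T}.

    ``counts`` rows are positions; probabilities are derived with a
    per-cell pseudocount of ``pseudocount * background(base)``.
    """

    name: str
    counts: tuple[tuple[float, float, float, float], ...]
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ValueError(f"PWM {self.name}: width must be >= 1")
        for row in self.counts:
            if len(row) != 4 or any(c < 0 for c in row):
                raise ValueError(f"PWM {self.name}: each position needs 4 non-negative counts")
            if sum(row) <= 0:
                raise ValueError(f"PWM {self.name}: zero-sum position")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    @property
    def width(self) -> int:
        return len(self.counts)

    def probabilities(self, background: Sequence[float] = UNIFORM_BG) -> np.ndarray:
        bg = np.asarray(background, dtype=float)
        mat = np.asarray(self.counts, dtype=float)
        num = mat + self.pseudocount * bg[None, :]
        return num / num.sum(axis=1, keepdims=True)

    def reverse_complement(self) -> "PWM":
        rc = tuple(tuple(row[::-1]) for row in self.counts[::-1])
        return PWM(self.name + "_rc", rc, self.pseudocount)

    def consensus(self) -> str:
        return "".join(BASES[int(np.argmax(row))] for row in self.counts)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    score: float
    pvalue: float


def _check_background(background: Sequence[float]) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 strictly positive probabilities")
    return bg / bg.sum()


def pwm_log_odds(pwm: PWM, background: Sequence[float] = UNIFORM_BG) -> np.ndarray:
    """Position x base log2-odds score matrix against the background."""
    bg = _check_background(background)
    return np.log2(pwm.probabilities(bg) / bg[None, :])


def score_distribution(
    pwm: PWM, background: Sequence[float] = UNIFORM_BG, epsilon: float = 1e-3
) -> tuple[dict[int, float], np.ndarray]:
    """Exact distribution of the integerized total score of a background word.

    Returns (distribution over integer scores in units of epsilon bits,
    integerized per-position score matrix).
    """
    bg = _check_background(background)
    lods = pwm_log_odds(pwm, bg)
    int_scores = np.rint(lods / epsilon).astype(np.int64)
    dist: dict[int, float] = {0: 1.0}
    for i in range(pwm.width):
        nxt: dict[int, float] = {}
        for total, p in dist.items():
            for b in range(4):
                key = total + int(int_scores[i, b])
                nxt[key] = nxt.get(key, 0.0) + p * bg[b]
        dist = nxt
    return dist, int_scores


def motif_score_pvalue(
    pwm: PWM,
    score: float,
    background: Sequence[float] = UNIFORM_BG,
    epsilon: float = 1e-3,
) -> float:
    """P(background word scores >= score); 0 above the max, 1 below the min."""
    dist, _ = score_distribution(pwm, background, epsilon)
    target = int(math.floor(score / epsilon + 0.5))
    return float(sum(p for s, p in dist.items() if s >= target))


def _survival(dist: dict[int, float]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array(sorted(dist), dtype=np.int64)
    probs = np.array([dist[int(s)] for s in scores])
    sf = probs[::-1].cumsum()[::-1]
    return scores, sf


def scan_sequence(
    seq: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: Sequence[float] | None = None,
    epsilon: float = 1e-3,
    sequence_id: str = "",
) -> list[MotifHit]:
    """Hits on both strands whose exact p-value is <= p_threshold.

    Windows containing N are skipped; reverse-strand windows are scored on
    the reverse complement.  Background defaults to uniform.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    seq = seq.upper()
    w = pwm.width
    if len(seq) < w:
        return []
    bg = _check_background(UNIFORM_BG if background is None else background)
    dist, int_scores = score_distribution(pwm, bg, epsilon)
    scores_sorted, sf = _survival(dist)

    def pvalue_of(int_total: int) -> float:
        idx = np.searchsorted(scores_sorted, int_total, side="left")
        return float(sf[idx]) if idx < len(sf) else 0.0

    rc_int = int_scores[::-1, ::-1]  # reverse-complement scoring matrix
    hits: list[MotifHit] = []
    encoded = np.array([BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)
    for off in range(len(seq) - w + 1):
        window = encoded[off : off + w]
        if (window < 0).any():
            continue
        for strand, mat in (("+", int_scores), ("-", rc_int)):
            total = int(mat[np.arange(w), window].sum())
            p = pvalue_of(total)
            if p <= p_threshold:
                hits.append(
                    MotifHit(sequence_id, off, strand, total * epsilon, p)
                )
    return hits


def estimate_background(sequences: Iterable[str]) -> tuple[float, float, float, float]:
    """0-order base frequencies of the scanned sequences (N ignored)."""
    counts = Counter()
    for seq in sequences:
        counts.update(b for b in seq.upper() if b in BASE_INDEX)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no A/C/G/T bases to estimate a background from")
    # floor at a tiny mass so log-odds stay finite on skewed toy data
    freqs = np.array([max(counts.get(b, 0) / total, 1e-6) for b in BASES])
    t = tuple(freqs / freqs.sum())
    return t  # type: ignore[return-value]


def peak_motif_proportion(
    peaks: Sequence,
    genome: Mapping[str, str],
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: Sequence[float] | None = None,
) -> tuple[float, list[bool]]:
    """Percentage of peaks containing >=1 motif hit on either strand.

    Background defaults to the 0-order frequencies of the peak sequences
    themselves.  Multiple hits within one peak do not change the proportion.
    """
    if not peaks:
        raise ValueError("no peaks to scan")
    seqs = []
    for p in peaks:
        if p.chrom not in genome:
            raise ValueError(f"peak {p.name or p.chrom}: contig {p.chrom} absent from genome")
        if p.end > len(genome[p.chrom]):
            raise ValueError(f"peak {p.name or p.chrom}:{p.start}-{p.end} beyond contig end")
        seqs.append(genome[p.chrom][p.start : p.end])
    bg = estimate_background(seqs) if background is None else background
    flags = [bool(scan_sequence(s, pwm, p_threshold, bg)) for s in seqs]
    return 100.0 * sum(flags) / len(flags), flags


def motif_set_association(
    peak_flags: Sequence[bool], control_flags: Sequence[bool]
) -> tuple[float, float]:
    """2x2 association of motif occurrence in peaks vs control sequences.

    Returns (odds ratio, two-sided Fisher exact p-value); the set-level
    analogue of suite-style motif enrichment reduced to per-sequence flags.
    """
    table = [
        [sum(peak_flags), len(peak_flags) - sum(peak_flags)],
        [sum(control_flags), len(control_flags) - sum(control_flags)],
    ]
    odds, p = fisher_exact(table)
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# Readers


def read_meme(path: str | Path, pseudocount: float = 0.1) -> list[PWM]:
    """Read motifs from MEME minimal motif format (letter-probability matrices)."""
    pwms: list[PWM] = []
    name = None
    rows: list[tuple[float, ...]] = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    pwms.append(PWM(name, tuple(rows), pseudocount))
                parts = line.split()
                name = parts[1] if len(parts) > 1 else f"motif_{len(pwms) + 1}"
                rows, in_matrix = [], False
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line:
                vals = line.split()
                if len(vals) == 4:
                    rows.append(tuple(float(v) for v in vals))
                else:
                    in_matrix = False
    if name is not None and rows:
        pwms.append(PWM(name, tuple(rows), pseudocount))
    if not pwms:
        raise ValueError(f"{path}: no motifs found")
    return pwms


def read_pfm(path: str | Path, name: str | None = None, pseudocount: float = 0.1) -> PWM:
    """Read a 4-row tab-separated position frequency matrix (rows A, C, G, T)."""
    with open(path) as fh:
        raw = [line.strip() for line in fh if line.strip() and not line.startswith((">", "#"))]
    if len(raw) != 4:
        raise ValueError(f"{path}: expected 4 rows (A, C, G, T), got {len(raw)}")
    rows = [tuple(float(v) for v in line.replace("\t", " ").split()) for line in raw]
    if len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: rows have unequal widths")
    counts = tuple(zip(*rows))
    return PWM(name or Path(path).stem, counts, pseudocount)
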