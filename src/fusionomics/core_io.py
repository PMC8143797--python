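"""Data model and readers/writers for the external formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals
(BED convention).  GTF input (1-based inclusive) is converted on read, so
every downstream distance computation uses a single arithmetic convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "ParseError",
    "GenomicInterval",
    "GeneModel",
    "DEGRecord",
    "PreyObservation",
    "GrowthCurve",
    "read_bed",
    "write_bed",
    "read_gtf",
    "read_deg_table",
    "write_deg_table",
    "read_prey_table",
    "write_prey_table",
    "read_growth_table",
    "write_growth_table",
    "read_fasta",
    "write_fasta",
    "write_report",
]

DNA_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file; message names the offending line where known."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval.

    ``score`` carries the peak caller's statistic (e.g. -log10 q) when the
    source file provides one; the pipeline never recomputes peak significance.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-aware transcriptional start site."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tx_end <= self.tx_start or self.tx_start < 0:
            raise ValueError(f"gene {self.gene_id}: invalid body [{self.tx_start}, {self.tx_end})")
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end or e <= s:
                raise ValueError(f"gene {self.gene_id}: exon [{s}, {e}) outside body")

    @property
    def tss(self) -> int:
        """Transcriptional start site: tx_start on +, tx_end - 1 on -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2fc: float
    pvalue: float
    padj: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"{self.gene_id}: pvalue {self.pvalue} outside [0, 1]")
        if self.padj is not None and not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"{self.gene_id}: padj {self.padj} outside [0, 1]")


@dataclass(frozen=True)
class PreyObservation:
    """One bait-prey row of a SAINT-style interaction table."""

    bait: str
    prey: str
    counts: tuple[int, ...]
    relative_abundance: float
    probability: float
    bfdr: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.bait}/{self.prey}: negative spectral count")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"{self.bait}/{self.prey}: probability outside [0, 1]")
        if not 0.0 <= self.bfdr <= 1.0:
            raise ValueError(f"{self.bait}/{self.prey}: bfdr outside [0, 1]")
        if self.relative_abundance < 0:
            raise ValueError(f"{self.bait}/{self.prey}: negative relative abundance")


@dataclass(frozen=True)
class GrowthCurve:
    """Absorbance time course for one construct replicate."""

    cell_line: str
    construct: str
    gene: str
    replicate: int
    readings: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        days = [d for d, _ in self.readings]
        if any(d < 0 for d in days):
            raise ValueError(f"{self.construct} rep {self.replicate}: negative day")
        if days != sorted(set(days)):
            raise ValueError(f"{self.construct} rep {self.replicate}: days not strictly increasing")
        if any(a <= 0 for _, a in self.readings):
            raise ValueError(f"{self.construct} rep {self.replicate}: absorbance must be positive")

    def absorbance_at(self, day: int) -> float:
        for d, a in self.readings:
            if d == day:
                return a
        raise KeyError(f"{self.construct} rep {self.replicate}: no reading at day {day}")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3-6/narrowPeak-like intervals.

    Columns 4 and 5 populate name and score when present; extra columns are
    ignored.  Coordinates are used exactly as in the file (already 0-based
    half-open).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            score = 0.0
            if len(fields) > 4 and fields[4] not in {"", "."}:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GTF


def _gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) == 2:
            attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene and exon rows of a GTF (GFF2-attribute dialect).

    GTF coordinates are 1-based inclusive and converted to 0-based half-open,
    so internal length equals (gtf_end - gtf_start + 1).
    """
    bodies: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_text = fields[:9]
            if feature not in {"gene", "exon"}:
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _gtf_attributes(attr_text)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                if gene_id in bodies:
                    raise ParseError(f"{path}:{lineno}: duplicate gene {gene_id}")
                bodies[gene_id] = (chrom, strand, start, end)
                order.append(gene_id)
            else:
                exons.setdefault(gene_id, []).append((start, end))

    genes: list[GeneModel] = []
    for gene_id in order:
        chrom, strand, start, end = bodies[gene_id]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                tx_start=start,
                tx_end=end,
                exons=tuple(sorted(exons.get(gene_id, []))),
            )
        )
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "fusionomics") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Tabular readers (TSV with headers)


def _read_tsv_rows(path: str | Path, required: Sequence[str]) -> Iterable[tuple[int, dict[str, str]]]:
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise ParseError(f"{path}: empty file, expected a header row")
        header = header_line.split("\t")
        missing = [c for c in required if c not in header]
        if missing:
            raise ParseError(f"{path}: missing required columns {missing}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            values = line.split("\t")
            if len(values) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} columns, got {len(values)}")
            yield lineno, dict(zip(header, values))


def read_deg_table(
    path: str | Path,
    gene_col: str = "gene_id",
    log2fc_col: str = "log2fc",
    pvalue_col: str = "pvalue",
    padj_col: str = "padj",
) -> list[DEGRecord]:
    """Read a differential-expression table. ``NA``/empty padj becomes missing."""
    records: list[DEGRecord] = []
    seen: set[str] = set()
    for lineno, row in _read_tsv_rows(path, [gene_col, log2fc_col, pvalue_col, padj_col]):
        gene = row[gene_col]
        if gene in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene!r}")
        seen.add(gene)
        padj_text = row[padj_col]
        padj = None if padj_text in {"", "NA", "NaN", "nan"} else float(padj_text)
        try:
            records.append(
                DEGRecord(gene, float(row[log2fc_col]), float(row[pvalue_col]), padj)
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_deg_table(records: Iterable[DEGRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tpvalue\tpadj\n")
        for r in records:
            padj = "NA" if r.padj is None else repr(r.padj)
            fh.write(f"{r.gene_id}\t{r.log2fc!r}\t{r.pvalue!r}\t{padj}\n")


def read_prey_table(path: str | Path) -> list[PreyObservation]:
    """Read a SAINT-style prey table.

    Expected columns: bait, prey, counts (replicate spectral counts joined by
    ``|``), relative_abundance, probability, bfdr.
    """
    rows: list[PreyObservation] = []
    cols = ["bait", "prey", "counts", "relative_abundance", "probability", "bfdr"]
    for lineno, row in _read_tsv_rows(path, cols):
        try:
            counts = tuple(int(c) for c in row["counts"].split("|"))
            rows.append(
                PreyObservation(
                    bait=row["bait"],
                    prey=row["prey"],
                    counts=counts,
                    relative_abundance=float(row["relative_abundance"]),
                    probability=float(row["probability"]),
                    bfdr=float(row["bfdr"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_prey_table(rows: Iterable[PreyObservation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bait\tprey\tcounts\trelative_abundance\tprobability\tbfdr\n")
        for r in rows:
            counts = "|".join(str(c) for c in r.counts)
            fh.write(
                f"{r.bait}\t{r.prey}\t{counts}\t{r.relative_abundance!r}\t"
                f"{r.probability!r}\t{r.bfdr!r}\n"
            )


def read_growth_table(path: str | Path) -> list[GrowthCurve]:
    """Read a long-format growth table.

    Expected columns: cell_line, construct, gene, replicate, day, absorbance;
    one row per reading, grouped into one curve per (construct, replicate).
    """
    readings: dict[tuple[str, str, str, int], list[tuple[int, float]]] = {}
    cols = ["cell_line", "construct", "gene", "replicate", "day", "absorbance"]
    for lineno, row in _read_tsv_rows(path, cols):
        try:
            key = (row["cell_line"], row["construct"], row["gene"], int(row["replicate"]))
            day, absorbance = int(row["day"]), float(row["absorbance"])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if day < 0:
            raise ParseError(f"{path}:{lineno}: negative day {day}")
        if absorbance <= 0:
            raise ParseError(f"{path}:{lineno}: absorbance must be positive, got {absorbance}")
        readings.setdefault(key, []).append((day, absorbance))
    curves = []
    for (cell_line, construct, gene, replicate), obs in readings.items():
        try:
            curves.append(
                GrowthCurve(cell_line, construct, gene, replicate, tuple(sorted(obs)))
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return curves


def write_growth_table(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_line\tconstruct\tgene\treplicate\tday\tabsorbance\n")
        for c in curves:
            for day, absorbance in c.readings:
                fh.write(
                    f"{c.cell_line}\t{c.construct}\t{c.gene}\t{c.replicate}\t{day}\t{absorbance!r}\n"
                )


# ---------------------------------------------------------------------------
# FASTA and reports


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read named sequences; upper-cased, alphabet restricted to A/C/G/T/N."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ParseError(f"{path}: sequence {record.id} has non-DNA characters {sorted(bad)}")
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_report(obj: object, path: str | Path) -> None:
    """Write a report object as JSON (``.json``) or TSV (anything else).

    TSV output expects a list of flat dicts sharing keys.
    """
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return
    if not isinstance(obj, list) or not obj or not isinstance(obj[0], dict):
        raise ValueError("TSV report requires a non-empty list of dicts")
    columns = list(obj[0])
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in obj:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
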