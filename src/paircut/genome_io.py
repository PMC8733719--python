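"""Genome and annotation I/O with coordinate-safe subsequence access.

Sequences are stored uppercase over the alphabet ``{A, C, G, T, N}``.  All
internal coordinates are 0-based half-open; GFF3 input (1-based inclusive)
is converted on ingest, and report writers convert back to 1-based for
output.  Annotation intervals support point queries that classify any
genomic position as exonic, intronic or intergenic — the three location
classes used when reporting off-target sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

VALID_ALPHABET = frozenset("ACGTN")

#: location classes, in precedence order (exon membership wins)
EXONIC = "exonic"
INTRONIC = "intronic"
INTERGENIC = "intergenic"


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass
class Genome:
    """A set of named nucleotide sequences.

    Attributes
    ----------
    records:
        Mapping of sequence id to uppercase nucleotide string.
    """

    records: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.records

    def __getitem__(self, seq_id: str) -> str:
        return self.records[seq_id]

    def add(self, seq_id: str, sequence: str) -> None:
        if seq_id in self.records:
            raise FastaError(f"duplicate sequence id {seq_id!r}")
        seq = sequence.upper()
        if not seq:
            raise FastaError(f"empty sequence for record {seq_id!r}")
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise FastaError(
                f"record {seq_id!r} contains invalid characters {sorted(bad)!r}"
            )
        self.records[seq_id] = seq

    def items(self) -> Iterable[tuple[str, str]]:
        return self.records.items()


def read_fasta(path: str | Path) -> Genome:
    """Read a multi-record FASTA file into a :class:`Genome`.

    Lowercase bases are uppercased; duplicate ids and empty files are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome = Genome()
    with open(path) as handle:
        first = handle.read(1)
        if not first:
            raise FastaError(f"{path}: empty file")
        if first != ">":
            raise FastaError(f"{path}: line 1: expected '>' header, got {first!r}")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            genome.add(record.id, str(record.seq))
    if not genome.records:
        raise FastaError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def fetch_subsequence(
    genome: Genome, seq_id: str, start: int, end: int, strand: str = "+"
) -> str:
    """Return ``genome[seq_id][start:end]``; reverse-complemented on ``-``.

    Coordinates are 0-based half-open and must satisfy
    ``0 <= start < end <= length``.
    """
    if seq_id not in genome:
        raise KeyError(f"unknown sequence id {seq_id!r}")
    seq = genome[seq_id]
    if not (0 <= start < end <= len(seq)):
        raise IndexError(
            f"interval [{start}, {end}) out of range for {seq_id!r} "
            f"(length {len(seq)})"
        )
    if strand not in {"+", "-"}:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    sub = seq[start:end]
    return sub if strand == "+" else reverse_complement(sub)


@dataclass
class Feature:
    seq_id: str
    start: int  # 0-based half-open
    end: int
    kind: str  # exon | intron | gene
    strand: str
    gene_id: str = ""


class AnnotationSet:
    """Interval annotation supporting exonic/intronic/intergenic point queries.

    Exons and gene spans are stored per contig in interval trees.  Introns
    need not be provided: any position inside a gene span but outside every
    exon is classed intronic.
    """

    def __init__(self, features: Iterable[Feature] = ()) -> None:
        self._exons: dict[str, IntervalTree] = {}
        self._genes: dict[str, IntervalTree] = {}
        self.features: list[Feature] = []
        for feat in features:
            self.add(feat)

    def add(self, feat: Feature) -> None:
        if feat.end <= feat.start:
            raise ValueError(f"empty interval for feature {feat!r}")
        self.features.append(feat)
        if feat.kind == "exon":
            self._exons.setdefault(feat.seq_id, IntervalTree()).addi(
                feat.start, feat.end, feat
            )
        elif feat.kind in {"gene", "mRNA"}:
            self._genes.setdefault(feat.seq_id, IntervalTree()).addi(
                feat.start, feat.end, feat
            )
        # intron features, if present, are implied by the gene/exon rule

    def annotate_position(self, genome: Genome, seq_id: str, pos: int) -> str:
        """Classify a single 0-based position.

        Exon membership wins; a position inside a gene but outside all
        exons is intronic; everything else is intergenic.
        """
        if seq_id not in genome:
            raise KeyError(f"unknown sequence id {seq_id!r}")
        if not (0 <= pos < len(genome[seq_id])):
            raise IndexError(f"position {pos} out of bounds for {seq_id!r}")
        if seq_id in self._exons and self._exons[seq_id][pos]:
            return EXONIC
        if seq_id in self._genes and self._genes[seq_id][pos]:
            return INTRONIC
        return INTERGENIC

    def annotate_interval(self, genome: Genome, seq_id: str, start: int, end: int) -> str:
        """Classify an interval by its most gene-proximal overlap.

        Returns exonic if any base overlaps an exon, else intronic if any
        base lies inside a gene, else intergenic.
        """
        if seq_id in self._exons and self._exons[seq_id].overlap(start, end):
            return EXONIC
        if seq_id in self._genes and self._genes[seq_id].overlap(start, end):
            return INTRONIC
        return INTERGENIC


_GFF_COLS = 9


def read_gff3(path: str | Path) -> AnnotationSet:
    """Parse gene/mRNA/exon features from a GFF3 file (other types ignored).

    GFF3 coordinates are 1-based inclusive and are converted to 0-based
    half-open on ingest.
    """
    path = Path(path)
    ann = AnnotationSet()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns")
            seq_id, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in {"gene", "mRNA", "exon"}:
                continue
            gene_id = ""
            m = re.search(r"(?:^|;)(?:ID|Parent)=([^;]+)", attrs)
            if m:
                gene_id = m.group(1)
            ann.add(
                Feature(
                    seq_id=seq_id,
                    start=int(start) - 1,
                    end=int(end),
                    kind=ftype,
                    strand=strand,
                    gene_id=gene_id,
                )
            )
    return ann


def write_gff3(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id}" if f.kind == "gene" else f"Parent={f.gene_id}"
            out.write(
                "\t".join(
                    [
                        f.seq_id,
                        "paircut",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def iter_bed(intervals: Iterable[tuple[str, int, int, str, float, str]]) -> Iterator[str]:
    """Yield BED6 lines from (seq_id, start, end, name, score, strand) tuples."""
    for seq_id, start, end, name, score, strand in intervals:
        yield f"{seq_id}\t{start}\t{end}\t{name}\t{score:g}\t{strand}"
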