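"""Shared genomic data model.

All coordinates are 0-based half-open internally; file readers and writers
convert at the boundary (GFF3 and VCF are 1-based inclusive, BED is 0-based
half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeSequence:
    """In-memory genome: chromosome id -> uppercase sequence over A,C,G,T,N."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = dict(sequences)
        self.lengths: dict[str, int] = {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); reverse-complemented when strand is '-'."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or start > end:
            raise ValueError(
                f"slice {start}-{end} outside {chrom} (length {self.lengths[chrom]})"
            )
        seq = self.sequences[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq

    def total_length(self) -> int:
        return sum(self.lengths.values())


@dataclass
class MrnaModel:
    """One transcript isoform: ordered exon chain plus CDS segments.

    Exons and CDS are lists of (start, end) tuples in genomic ascending order,
    disjoint within each list; CDS space is a subset of exon space.
    """

    mrna_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for segs, label in ((self.exons, "exons"), (self.cds, "CDS")):
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.mrna_id}: overlapping {label} segments")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic ascending."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def junction_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(self.introns())


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    mrnas: list[MrnaModel] = field(default_factory=list)

    @property
    def is_protein_coding(self) -> bool:
        return any(m.cds for m in self.mrnas)

    @property
    def span(self) -> tuple[int, int]:
        """Transcribed region: union span of all mRNA exon chains (UTRs in)."""
        return (
            min(m.span[0] for m in self.mrnas),
            max(m.span[1] for m in self.mrnas),
        )

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    def representative_mrna(self) -> MrnaModel:
        """Longest total CDS; ties broken by exon span, then mrna_id."""
        return max(
            self.mrnas,
            key=lambda m: (m.cds_length, m.span[1] - m.span[0], _neg_lex(m.mrna_id)),
        )

    def cds_union(self) -> list[tuple[int, int]]:
        """Merged CDS segments over all isoforms."""
        return merge_intervals(seg for m in self.mrnas for seg in m.cds)

    def exon_union(self) -> list[tuple[int, int]]:
        return merge_intervals(seg for m in self.mrnas for seg in m.exons)


def _neg_lex(s: str) -> tuple[int, ...]:
    # max() with lexicographically *smallest* id winning ties
    return tuple(-ord(c) for c in s)


@dataclass
class Annotation:
    """A gene set on one genome coordinate frame."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    orphan_features: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene id {gene.gene_id}")
        self.genes[gene.gene_id] = gene

    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self if g.is_protein_coding]

    def chromosomes(self) -> set[str]:
        return {g.chrom for g in self}

    def sorted_genes(self) -> list[GeneModel]:
        return sorted(self.genes.values(), key=lambda g: (g.chrom, g.span, g.gene_id))


@dataclass
class TranscriptModel:
    """An aligned full-length read: chrom, strand, ordered exon blocks."""

    read_id: str
    chrom: str
    strand: str  # '+', '-' or '.' (unstranded)
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = _merge_bookended(sorted(self.exons))

    @property
    def stranded(self) -> bool:
        return self.strand in ("+", "-")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junction_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered intron (start, end) pairs between exon blocks."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    def genomic_to_spliced(self, pos: int) -> int | None:
        """Map a genomic position inside an exon to its offset along the
        spliced transcript in transcription order; None if intronic/outside."""
        off = 0
        exons = self.exons if self.strand != "-" else self.exons[::-1]
        for s, e in exons:
            if s <= pos < e:
                return off + (pos - s if self.strand != "-" else e - 1 - pos)
            off += e - s
        return None


@dataclass(frozen=True)
class VariantRecord:
    """One REF->ALT change; multi-allelic VCF records are split upstream.

    ``pos`` is 0-based; ``span`` is the affected reference footprint
    [pos, pos + len(ref)) — a 1-bp anchor for pure insertions.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str  # 'SNP' | 'indel' | 'SV'
    variant_id: str = "."
    flagged: bool = False

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.pos, self.pos + max(1, len(self.ref)))


def merge_intervals(segs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended (start, end) pairs."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(segs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _merge_bookended(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in segs:
        if out and s <= out[-1][1]:  # book-ended or overlapping blocks
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
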