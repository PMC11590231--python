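"""Intron extraction and splice-site dinucleotide census.

An intron's donor is its first two bases and its acceptor its last two bases
in transcription order (reverse-complemented for minus-strand genes). The
canonical pair is GT-AG; every other pair is non-canonical. Types containing
N are reported separately and excluded from donor/acceptor type counts.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .model import Annotation, GenomeSequence, reverse_complement

logger = logging.getLogger(__name__)

CANONICAL = "GT-AG"


@dataclass(frozen=True)
class Intron:
    """A spliced-out genomic interval with transcribed-strand boundary
    dinucleotides; ``splice_type`` is always ``donor + '-' + acceptor``."""

    chrom: str
    start: int
    end: int
    strand: str
    donor: str
    acceptor: str
    gene_id: str
    mrna_id: str

    @property
    def splice_type(self) -> str:
        return f"{self.donor}-{self.acceptor}"

    @property
    def is_canonical(self) -> bool:
        return self.splice_type == CANONICAL

    @property
    def has_n(self) -> bool:
        return "N" in self.donor or "N" in self.acceptor


def extract_introns(
    ann: Annotation,
    genome: GenomeSequence,
    dedup_scope: Literal["gene", "isoform"] = "gene",
) -> list[Intron]:
    """Extract introns as gaps between consecutive exons of each mRNA.

    Under ``dedup_scope='gene'`` (default) identical (start, end) introns
    shared by several isoforms of one gene count once; the same coordinates
    in two different genes count twice. ``'isoform'`` counts every mRNA's
    introns. Introns shorter than 4 bp (donor and acceptor would overlap)
    are excluded and logged.
    """
    out: list[Intron] = []
    n_short = 0
    for gene in ann.sorted_genes():
        seen: set[tuple[int, int]] = set()
        for mrna in gene.mrnas:
            for s, e in mrna.introns():
                if dedup_scope == "gene":
                    if (s, e) in seen:
                        continue
                    seen.add((s, e))
                if e - s < 4:
                    n_short += 1
                    continue
                if gene.strand == "+":
                    donor = genome.fetch(gene.chrom, s, s + 2)
                    acceptor = genome.fetch(gene.chrom, e - 2, e)
                else:
                    donor = reverse_complement(genome.fetch(gene.chrom, e - 2, e))
                    acceptor = reverse_complement(genome.fetch(gene.chrom, s, s + 2))
                out.append(
                    Intron(gene.chrom, s, e, gene.strand, donor, acceptor,
                           gene.gene_id, mrna.mrna_id)
                )
    if n_short:
        logger.warning("%d introns shorter than 4 bp excluded", n_short)
    return out


@dataclass
class SpliceCensus:
    """Counts and shares of splice-site dinucleotide pairs.

    ``n_donor_types`` / ``n_acceptor_types`` count distinct donors/acceptors
    over unambiguous non-canonical types only. ``gene_counts`` maps gene id
    to its number of non-canonical introns.
    """

    counts: dict[str, int]
    total: int
    n_flagged_n: int = 0
    gene_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ratios(self) -> dict[str, float]:
        return {t: 100.0 * n / self.total for t, n in self.counts.items()}

    @property
    def canonical_percent(self) -> float:
        return self.ratios.get(CANONICAL, 0.0)

    @property
    def noncanonical_percent(self) -> float:
        return 100.0 * self.noncanonical_total / self.total

    @property
    def noncanonical_total(self) -> int:
        return self.total - self.counts.get(CANONICAL, 0)

    @property
    def n_noncanonical_types(self) -> int:
        return sum(
            1 for t in self.counts if t != CANONICAL and "N" not in t
        )

    @property
    def n_donor_types(self) -> int:
        return len(
            {t.split("-")[0] for t in self.counts if t != CANONICAL and "N" not in t}
        )

    @property
    def n_acceptor_types(self) -> int:
        return len(
            {t.split("-")[1] for t in self.counts if t != CANONICAL and "N" not in t}
        )

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "SpliceCensus":
        """Build a census straight from a type -> count table (e.g. a
        published census table)."""
        if not counts:
            raise ValueError("empty count table")
        return cls(counts=dict(counts), total=sum(counts.values()))

    def to_dataframe(self, others_below_percent: float | None = 0.01) -> pd.DataFrame:
        """Census table sorted by count descending (ties lexicographic); types
        whose share falls below ``others_below_percent`` collapse into an
        'Others' row, as is conventional for splice-site reports."""
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        rows, others = [], 0
        for t, n in items:
            ratio = 100.0 * n / self.total
            if (
                others_below_percent is not None
                and t != CANONICAL
                and ratio < others_below_percent
            ):
                others += n
            else:
                rows.append({"type": t, "count": n, "ratio_percent": ratio})
        if others:
            rows.append(
                {"type": "Others", "count": others,
                 "ratio_percent": 100.0 * others / self.total}
            )
        return pd.DataFrame(rows, columns=["type", "count", "ratio_percent"])


def build_census(introns: Sequence[Intron]) -> SpliceCensus:
    """Tabulate splice types over a nonempty intron collection."""
    if not introns:
        raise ValueError("cannot build a census from zero introns")
    counts = Counter(i.splice_type for i in introns)
    gene_counts: dict[str, int] = defaultdict(int)
    for i in introns:
        if not i.is_canonical:
            gene_counts[i.gene_id] += 1
    n_flagged = sum(1 for i in introns if i.has_n)
    if n_flagged:
        logger.warning("%d introns have N at donor/acceptor", n_flagged)
    return SpliceCensus(
        counts=dict(counts),
        total=len(introns),
        n_flagged_n=n_flagged,
        gene_counts=dict(gene_counts),
    )


def per_gene_noncanonical(introns: Sequence[Intron]) -> dict[str, int]:
    """How many genes carry exactly one vs two-or-more non-canonical introns."""
    per_gene: dict[str, int] = defaultdict(int)
    for i in introns:
        if not i.is_canonical:
            per_gene[i.gene_id] += 1
    ones = sum(1 for n in per_gene.values() if n == 1)
    twos = sum(1 for n in per_gene.values() if n >= 2)
    return {
        "genes_with_1": ones,
        "genes_with_2plus": twos,
        "genes_total": ones + twos,
    }


def gene_involvement_total(genes_with_1: int, genes_with_2plus: int) -> int:
    """Total genes carrying non-canonical sites, from the two-bin breakdown."""
    return genes_with_1 + genes_with_2plus
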