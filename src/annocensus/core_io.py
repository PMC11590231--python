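"""Readers and writers for FASTA, GFF3, BED12 and VCF, plus interval algebra
and annotation diffing.

Conversions between file conventions (GFF3/VCF 1-based inclusive, BED 0-based
half-open) and the internal 0-based half-open convention happen here and only
here. All writers emit deterministic ordering (chrom, start, id) so identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

from .model import (
    Annotation,
    GeneModel,
    GenomeSequence,
    Interval,
    MrnaModel,
    TranscriptModel,
    VariantRecord,
)
from .variant_census import classify_variant

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> GenomeSequence:
    """Load a FASTA genome; uppercase, U->T, any other non-ACGTN base -> N.

    Raises on duplicate chromosome ids and on empty files.
    """
    sequences: dict[str, str] = {}
    n_warn = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate chromosome id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        cleaned = _NON_ACGTN.sub("N", seq)
        n_warn += sum(1 for a, b in zip(seq, cleaned) if a != b)
        sequences[rec.id] = cleaned
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    if n_warn:
        logger.warning("%d non-ACGTN bases replaced with N while reading %s", n_warn, path)
    return GenomeSequence(sequences)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, genome: GenomeSequence | None = None) -> Annotation:
    """Parse a GFF3 gene/mRNA/exon/CDS hierarchy into an :class:`Annotation`.

    GFF3 1-based inclusive coordinates become 0-based half-open. Exons whose
    gene ancestor cannot be resolved are collected in ``orphan_features``, not
    silently dropped. With a genome supplied, features outside chromosome
    bounds raise, naming the offending feature.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    ann = Annotation()
    claimed_exon_parents: set[str] = set()
    for g in db.features_of_type("gene"):
        gene = GeneModel(gene_id=g.id, chrom=g.seqid, strand=g.strand)
        for m in db.children(g, featuretype=("mRNA", "transcript"), level=1):
            exons = [(e.start - 1, e.end) for e in db.children(m, featuretype="exon")]
            cds = [(c.start - 1, c.end) for c in db.children(m, featuretype="CDS")]
            if not exons:
                raise ValueError(f"mRNA {m.id} has zero exons")
            claimed_exon_parents.add(m.id)
            mrna = MrnaModel(mrna_id=m.id, exons=exons, cds=cds, strand=g.strand)
            if genome is not None:
                lim = genome.lengths.get(g.seqid)
                if lim is None:
                    raise ValueError(f"gene {g.id}: unknown chromosome {g.seqid}")
                if mrna.span[0] < 0 or mrna.span[1] > lim:
                    raise ValueError(
                        f"feature {m.id} at {g.seqid}:{mrna.span} exceeds "
                        f"chromosome length {lim}"
                    )
            gene.mrnas.append(mrna)
        if gene.mrnas:
            ann.add(gene)
    for e in db.features_of_type("exon"):
        parents = e.attributes.get("Parent", [])
        if not parents or not any(p in claimed_exon_parents for p in parents):
            ann.orphan_features.append(e.id)
    if ann.orphan_features:
        logger.warning("%d orphan exon features in %s", len(ann.orphan_features), path)
    return ann


def write_annotation(ann: Annotation, path: str | Path, source: str = "annocensus") -> None:
    """Write gene/mRNA/exon/CDS GFF3 (1-based inclusive) deterministically."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in ann.sorted_genes():
            gs, ge = gene.span
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{gs + 1}\t{ge}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for m in sorted(gene.mrnas, key=lambda m: (m.span, m.mrna_id)):
                ms, me = m.span
                fh.write(
                    f"{gene.chrom}\t{source}\tmRNA\t{ms + 1}\t{me}\t.\t{gene.strand}\t.\t"
                    f"ID={m.mrna_id};Parent={gene.gene_id}\n"
                )
                for i, (s, e) in enumerate(m.exons, 1):
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                        f"ID={m.mrna_id}.exon{i};Parent={m.mrna_id}\n"
                    )
                for i, (s, e) in enumerate(m.cds, 1):
                    fh.write(
                        f"{gene.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t0\t"
                        f"ID={m.mrna_id}.cds{i};Parent={m.mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# Transcript models (BED12 or GFF3)
# ---------------------------------------------------------------------------

@dataclass
class TranscriptSet:
    """Transcript models plus the count of unstranded reads that were set
    aside (strand '.'); those are excluded from strand-dependent analyses."""

    transcripts: list[TranscriptModel] = field(default_factory=list)
    n_unstranded: int = 0

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self):
        return len(self.transcripts)

    def stranded(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.stranded]


def read_transcripts(path: str | Path) -> TranscriptSet:
    """Read full-length transcript models from BED12 or GFF3.

    Book-ended exon blocks are merged. Transcripts with strand '.' are kept
    but flagged unstranded and counted.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3", ".gtf"):
        return _read_transcripts_gff3(path)
    return _read_transcripts_bed12(path)


def _read_transcripts_bed12(path: Path) -> TranscriptSet:
    ts = TranscriptSet()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"expected BED12, got {len(f)} columns in {path}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"BED12 block count mismatch for {name}")
            exons = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            if strand not in ("+", "-"):
                strand = "."
                ts.n_unstranded += 1
            ts.transcripts.append(TranscriptModel(name, chrom, strand, exons))
    if ts.n_unstranded:
        logger.warning(
            "%d unstranded transcripts in %s excluded from strand-dependent analyses",
            ts.n_unstranded, path,
        )
    return ts


def _read_transcripts_gff3(path: Path) -> TranscriptSet:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    ts = TranscriptSet()
    for m in db.features_of_type(("mRNA", "transcript")):
        exons = [(e.start - 1, e.end) for e in db.children(m, featuretype="exon")]
        if not exons:
            continue
        strand = m.strand if m.strand in ("+", "-") else "."
        if strand == ".":
            ts.n_unstranded += 1
        ts.transcripts.append(TranscriptModel(m.id, m.seqid, strand, exons))
    return ts


def write_transcripts(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as BED12, sorted by (chrom, start, id)."""
    rows = sorted(transcripts, key=lambda t: (t.chrom, t.span, t.read_id))
    with open(path, "w") as fh:
        for t in rows:
            s, e = t.span
            sizes = ",".join(str(b - a) for a, b in t.exons)
            starts = ",".join(str(a - s) for a, _ in t.exons)
            fh.write(
                f"{t.chrom}\t{s}\t{e}\t{t.read_id}\t0\t{t.strand}\t{s}\t{e}\t0\t"
                f"{len(t.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variants(
    path: str | Path, genome: GenomeSequence | None = None
) -> list[VariantRecord]:
    """Read VCF 4.x; multi-allelic records become one record per ALT allele.

    With a genome supplied, REF alleles inconsistent with it are logged as
    warnings but the records are kept.
    """
    out: list[VariantRecord] = []
    mismatches: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            pos0 = rec.pos - 1
            ref = rec.ref or ""
            if genome is not None and rec.chrom in genome:
                actual = genome.fetch(rec.chrom, pos0, min(pos0 + len(ref), genome.lengths[rec.chrom]))
                if actual != ref:
                    mismatches.append(f"{rec.chrom}:{rec.pos}")
            for alt in rec.alts or ():
                cls, flagged = classify_variant(ref, alt)
                out.append(
                    VariantRecord(
                        chrom=rec.chrom, pos=pos0, ref=ref, alt=str(alt),
                        var_class=cls, variant_id=rec.id or ".", flagged=flagged,
                    )
                )
    if mismatches:
        logger.warning(
            "%d REF alleles inconsistent with supplied genome (first: %s)",
            len(mismatches), mismatches[0],
        )
    return out


def write_variants(
    variants: Sequence[VariantRecord],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal site-only VCF 4.2 file, sorted by (chrom, pos)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">\n')
        if contig_lengths:
            for c in sorted(contig_lengths):
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t"
                f"VC={v.var_class}\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def interval_union_length(intervals: Iterable[Interval | tuple]) -> int:
    """Total bp covered by the union of intervals; overlap-tolerant."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        if isinstance(iv, Interval):
            by_chrom[iv.chrom].append((iv.start, iv.end))
        else:
            chrom, start, end = iv[0], iv[1], iv[2]
            by_chrom[chrom].append((start, end))
    total = 0
    for segs in by_chrom.values():
        segs.sort()
        cur_s, cur_e = segs[0]
        for s, e in segs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def build_interval_tree(segs: Iterable[tuple[int, int, object]]) -> IntervalTree:
    tree = IntervalTree()
    for s, e, data in segs:
        if e > s:
            tree.addi(s, e, data)
    return tree


# ---------------------------------------------------------------------------
# Annotation diffing
# ---------------------------------------------------------------------------

@dataclass
class AnnotationDiff:
    """Feature-level difference between two gene sets on one genome.

    An exon or intron is a unique (chrom, start, end, strand) tuple over the
    whole annotation; a deleted/added locus is a gene none of whose exons
    shares coordinates with any exon of the other gene set.
    """

    exons_deleted: list[tuple] = field(default_factory=list)
    exons_added: list[tuple] = field(default_factory=list)
    introns_deleted: list[tuple] = field(default_factory=list)
    introns_added: list[tuple] = field(default_factory=list)
    loci_deleted: list[str] = field(default_factory=list)
    loci_added: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "exons_deleted": len(self.exons_deleted),
            "exons_added": len(self.exons_added),
            "introns_deleted": len(self.introns_deleted),
            "introns_added": len(self.introns_added),
            "loci_deleted": len(self.loci_deleted),
            "loci_added": len(self.loci_added),
        }


def _exon_set(ann: Annotation) -> set[tuple]:
    return {
        (g.chrom, s, e, g.strand) for g in ann for m in g.mrnas for s, e in m.exons
    }


def _intron_set(ann: Annotation) -> set[tuple]:
    return {
        (g.chrom, s, e, g.strand)
        for g in ann
        for m in g.mrnas
        for s, e in m.introns()
    }


def diff_annotations(a: Annotation, b: Annotation) -> AnnotationDiff:
    """Compare gene sets *a* (before) and *b* (after) on the same genome."""
    chroms_a, chroms_b = a.chromosomes(), b.chromosomes()
    if chroms_a and chroms_b and not (chroms_a & chroms_b):
        raise ValueError(
            f"annotations share no chromosomes: {sorted(chroms_a)} vs {sorted(chroms_b)}"
        )
    ex_a, ex_b = _exon_set(a), _exon_set(b)
    in_a, in_b = _intron_set(a), _intron_set(b)
    diff = AnnotationDiff(
        exons_deleted=sorted(ex_a - ex_b),
        exons_added=sorted(ex_b - ex_a),
        introns_deleted=sorted(in_a - in_b),
        introns_added=sorted(in_b - in_a),
    )
    diff.loci_deleted = _novel_loci(a, b)
    diff.loci_added = _novel_loci(b, a)
    return diff


def _novel_loci(query: Annotation, subject: Annotation) -> list[str]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in subject:
        for m in g.mrnas:
            for s, e in m.exons:
                trees[g.chrom].addi(s, e)
    out = []
    for g in query:
        tree = trees.get(g.chrom)
        hit = tree is not None and any(
            tree.overlap(s, e) for m in g.mrnas for s, e in m.exons
        )
        if not hit:
            out.append(g.gene_id)
    return sorted(out)
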