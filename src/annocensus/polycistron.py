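"""Polycistronic-locus identification from full-length transcript models.

A polycistronic locus is an ordered run of two or more protein-coding genes
(PCGs) on one strand that at least one full-length transcript co-covers: the
read's exon blocks cover each member's CDS union at or above a coverage
threshold. Evidence transcripts whose covered-gene sets overlap are merged
into one locus (connected components), so a locus is counted once even when
different reads cover two vs three of its genes. Opposite-strand coverage
never counts toward membership.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import (
    Annotation,
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    merge_intervals,
    reverse_complement,
)
from .stats import welch_t_test

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


# ---------------------------------------------------------------------------
# Gene coverage by transcripts
# ---------------------------------------------------------------------------

class GeneIndex:
    """Per-(chrom, strand) interval tree over coding genes' spans, with the
    CDS union cached per gene."""

    def __init__(self, ann: Annotation):
        self.ann = ann
        self.trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self.cds_union: dict[str, list[tuple[int, int]]] = {}
        for g in ann.coding_genes():
            s, e = g.span
            self.trees[(g.chrom, g.strand)].addi(s, e, g.gene_id)
            self.cds_union[g.gene_id] = g.cds_union()

    def candidates(self, t: TranscriptModel) -> list[str]:
        tree = self.trees.get((t.chrom, t.strand))
        if tree is None:
            return []
        s, e = t.span
        return [hit.data for hit in tree.overlap(s, e)]


def _covered_bp(exons: Sequence[tuple[int, int]], segs: Sequence[tuple[int, int]]) -> int:
    total = 0
    for cs, ce in segs:
        for es, ee in exons:
            lo, hi = max(cs, es), min(ce, ee)
            if hi > lo:
                total += hi - lo
    return total


def assign_covered_genes(
    transcript: TranscriptModel,
    ann: Annotation,
    min_cds_coverage: float = 0.5,
    index: GeneIndex | None = None,
) -> list[str]:
    """Coding genes on the transcript's strand whose CDS union the exon
    blocks cover at >= ``min_cds_coverage``, ordered 5'->3' in transcription
    order. Unstranded transcripts cover nothing."""
    if not transcript.stranded:
        return []
    idx = index or GeneIndex(ann)
    hits = []
    for gid in idx.candidates(transcript):
        cds = idx.cds_union[gid]
        total = sum(e - s for s, e in cds)
        if total and _covered_bp(transcript.exons, cds) / total >= min_cds_coverage:
            hits.append(gid)
    hits.sort(key=lambda gid: idx.cds_union[gid][0][0])
    if transcript.strand == "-":
        hits.reverse()
    return hits


# ---------------------------------------------------------------------------
# Locus detection
# ---------------------------------------------------------------------------

@dataclass
class PolycistronicLocus:
    locus_id: str
    chrom: str
    strand: str
    member_genes: list[str]  # 5'->3' in transcription order
    supporting: list[TranscriptModel] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.supporting)

    @property
    def n_members(self) -> int:
        return len(self.member_genes)

    @property
    def mrna_lengths(self) -> list[int]:
        return [t.spliced_length for t in self.supporting]


def detect_polycistrons(
    transcripts: Iterable[TranscriptModel],
    ann: Annotation,
    min_cds_coverage: float = 0.5,
    min_support: int = 1,
) -> list[PolycistronicLocus]:
    """Merge transcripts covering >= 2 coding genes into polycistronic loci.

    Loci are connected components over shared covered-gene sets; each gene
    belongs to at most one locus. Loci supported by fewer than
    ``min_support`` reads are dropped.
    """
    idx = GeneIndex(ann)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    evidence: list[tuple[TranscriptModel, list[str]]] = []
    for t in transcripts:
        covered = assign_covered_genes(t, ann, min_cds_coverage, index=idx)
        if len(covered) >= 2:
            evidence.append((t, covered))
            for gid in covered:
                parent.setdefault(gid, gid)
            for a, b in zip(covered, covered[1:]):
                union(a, b)

    members: dict[str, list[str]] = defaultdict(list)
    for gid in parent:
        members[find(gid)].append(gid)
    comp_reads: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t, covered in evidence:
        comp_reads[find(covered[0])].append(t)

    loci: list[PolycistronicLocus] = []
    drafts = []
    for root, gids in members.items():
        gene0 = ann[gids[0]]
        gids.sort(key=lambda gid: idx.cds_union[gid][0][0])
        if gene0.strand == "-":
            gids.reverse()
        drafts.append((gene0.chrom, min(ann[g].span[0] for g in gids), gids,
                       gene0.strand, comp_reads[root]))
    drafts.sort(key=lambda d: (d[0], d[1], d[2][0]))
    for i, (chrom, _, gids, strand, reads) in enumerate(drafts, 1):
        if len(reads) < min_support:
            continue
        reads = sorted(reads, key=lambda t: (t.span, t.read_id))
        loci.append(
            PolycistronicLocus(f"pcl_{i:04d}", chrom, strand, gids, reads)
        )
    return loci


# ---------------------------------------------------------------------------
# Linkers, stop codons, frames, motifs
# ---------------------------------------------------------------------------

def _cds_bounds(gene: GeneModel) -> tuple[int, int]:
    union = gene.cds_union()
    return union[0][0], union[-1][1]


def linker_intervals(locus: PolycistronicLocus, ann: Annotation) -> list[tuple[int, int] | None]:
    """Genomic interval between consecutive members' CDS ends/starts in
    transcription order; None when the CDSs overlap (negative linker)."""
    out: list[tuple[int, int] | None] = []
    for up_id, down_id in zip(locus.member_genes, locus.member_genes[1:]):
        up, down = _cds_bounds(ann[up_id]), _cds_bounds(ann[down_id])
        if locus.strand == "+":
            s, e = up[1], down[0]
        else:
            s, e = down[1], up[0]
        out.append((s, e) if e > s else None)
    return out


def linker_regions(
    locus: PolycistronicLocus,
    ann: Annotation,
    genome: GenomeSequence,
    mode: Literal["genomic", "spliced"] = "spliced",
) -> list[str]:
    """Linker sequences (transcribed strand) per adjacent member pair.

    ``genomic`` returns the genomic span; ``spliced`` (default) the
    supporting transcript's exonic sequence within that span — the form the
    RNA actually carries, which is what linker motif scanning should see.
    Overlapping CDSs give an empty string.
    """
    out: list[str] = []
    for iv in linker_intervals(locus, ann):
        if iv is None:
            logger.warning("%s: negative-length linker", locus.locus_id)
            out.append("")
            continue
        s, e = iv
        if mode == "genomic":
            out.append(genome.fetch(locus.chrom, s, e, locus.strand))
            continue
        read = _best_covering_read(locus, s, e)
        if read is None:
            logger.warning(
                "%s: no supporting read spans linker %d-%d; genomic fallback",
                locus.locus_id, s, e,
            )
            out.append(genome.fetch(locus.chrom, s, e, locus.strand))
            continue
        pieces = [
            genome.fetch(locus.chrom, max(s, es), min(e, ee))
            for es, ee in read.exons
            if min(e, ee) > max(s, es)
        ]
        seq = "".join(pieces)
        out.append(reverse_complement(seq) if locus.strand == "-" else seq)
    return out


def _best_covering_read(locus: PolycistronicLocus, s: int, e: int) -> TranscriptModel | None:
    covering = [t for t in locus.supporting if t.span[0] <= s and t.span[1] >= e]
    if not covering:
        return None
    return max(covering, key=lambda t: (t.spliced_length, t.read_id))


def stop_codon_usage(
    ann: Annotation,
    genome: GenomeSequence,
    gene_subset: Iterable[str] | None = None,
) -> dict[str, float]:
    """Frequency of TAA / TAG / TGA / other terminal codons over the
    representative mRNA of each (coding) gene; frequencies sum to 1.

    Genes whose representative CDS is shorter than 3 nt are excluded."""
    genes = (
        [ann[g] for g in gene_subset] if gene_subset is not None else ann.coding_genes()
    )
    counts = Counter()
    n_excluded = 0
    for g in genes:
        m = g.representative_mrna()
        if m.cds_length < 3:
            n_excluded += 1
            continue
        seq = "".join(genome.fetch(g.chrom, s, e) for s, e in m.cds)
        if g.strand == "-":
            seq = reverse_complement(seq)
        stop = seq[-3:]
        counts[stop if stop in ("TAA", "TAG", "TGA") else "other"] += 1
    if n_excluded:
        logger.warning("%d genes with CDS < 3 nt excluded from stop-codon census", n_excluded)
    total = sum(counts.values())
    return {
        c: (counts.get(c, 0) / total if total else 0.0)
        for c in ("TAA", "TAG", "TGA", "other")
    }


def _cds_start_position(gene: GeneModel) -> int:
    """Genomic position of the first transcribed CDS base."""
    lo, hi = _cds_bounds(gene)
    return lo if gene.strand == "+" else hi - 1


def relative_frames(
    locus: PolycistronicLocus,
    ann: Annotation,
    transcript: TranscriptModel | None = None,
) -> list[dict]:
    """Relative reading frame per adjacent member pair, measured along the
    spliced supporting transcript (introns in linkers would otherwise
    scramble the frame): (spliced distance between CDS starts) mod 3;
    in-frame iff 0. Pairs whose CDS starts fall outside the read's exons
    are skipped and flagged."""
    out: list[dict] = []
    for up_id, down_id in zip(locus.member_genes, locus.member_genes[1:]):
        read = transcript
        if read is None:
            up_pos_ = _cds_start_position(ann[up_id])
            down_pos_ = _cds_start_position(ann[down_id])
            lo, hi = min(up_pos_, down_pos_), max(up_pos_, down_pos_)
            read = _best_covering_read(locus, lo, hi + 1)
        entry = {"pair": (up_id, down_id), "frame": None, "in_frame": None,
                 "skipped": False}
        if read is None:
            entry["skipped"] = True
            out.append(entry)
            continue
        up_off = read.genomic_to_spliced(_cds_start_position(ann[up_id]))
        down_off = read.genomic_to_spliced(_cds_start_position(ann[down_id]))
        if up_off is None or down_off is None:
            entry["skipped"] = True
        else:
            frame = (down_off - up_off) % 3
            entry.update(frame=frame, in_frame=frame == 0)
        out.append(entry)
    return out


def iupac_to_regex(motif: str) -> str:
    try:
        return "".join(IUPAC[c] for c in motif.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r} in motif") from exc


def scan_motif(linker_sequences: Sequence[str], motif: str) -> float:
    """Fraction of sequences containing >= 1 exact IUPAC-compatible match of
    the motif on the given (sense) strand."""
    pat = re.compile(iupac_to_regex(motif))
    if not linker_sequences:
        return 0.0
    n_hit = sum(1 for s in linker_sequences if pat.search(s.upper()))
    return n_hit / len(linker_sequences)


# ---------------------------------------------------------------------------
# Locus-level statistics
# ---------------------------------------------------------------------------

def adjacent_gene_gaps(ann: Annotation) -> dict[tuple[str, str], int]:
    """Gap (end -> start, floored at 0) between consecutive coding genes'
    transcribed spans along each chromosome."""
    gaps: dict[tuple[str, str], int] = {}
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in ann.coding_genes():
        by_chrom[g.chrom].append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.span)
        for a, b in zip(genes, genes[1:]):
            gaps[(a.gene_id, b.gene_id)] = max(0, b.span[0] - a.span[1])
    return gaps


def polycistron_stats(
    loci: Sequence[PolycistronicLocus],
    ann: Annotation,
    genome: GenomeSequence,
) -> dict:
    """Locus breakdown and comparative statistics of member vs non-member
    coding genes: protein length, adjacent-pair distance, stop-codon usage
    and the in-frame fraction of adjacent member pairs."""
    breakdown = Counter(l.n_members for l in loci)
    pcg_total = sum(k * n for k, n in breakdown.items())
    members = {g for l in loci for g in l.member_genes}
    mono = [g.gene_id for g in ann.coding_genes() if g.gene_id not in members]

    def protein_len(gid: str) -> float:
        return ann[gid].representative_mrna().cds_length / 3 - 1

    poly_prot = [protein_len(g) for g in sorted(members)]
    mono_prot = [protein_len(g) for g in mono]

    gaps = adjacent_gene_gaps(ann)
    poly_pairs = {
        tuple(sorted((a, b)))
        for l in loci
        for a, b in zip(l.member_genes, l.member_genes[1:])
    }
    poly_gaps, other_gaps = [], []
    for (a, b), gap in gaps.items():
        (poly_gaps if tuple(sorted((a, b))) in poly_pairs else other_gaps).append(gap)

    mrna_lengths = [ln for l in loci for ln in l.mrna_lengths]
    frames = [
        f for l in loci for f in relative_frames(l, ann) if not f["skipped"]
    ]
    n_in_frame = sum(1 for f in frames if f["in_frame"])

    def safe_test(a, b):
        try:
            return welch_t_test(a, b)
        except ValueError:
            return None

    return {
        "n_loci": len(loci),
        "breakdown": dict(sorted(breakdown.items())),
        "pcg_total": pcg_total,
        "mrna_length": {
            "mean": float(np.mean(mrna_lengths)) if mrna_lengths else None,
            "min": min(mrna_lengths) if mrna_lengths else None,
            "max": max(mrna_lengths) if mrna_lengths else None,
        },
        "protein_length": {
            "mean_poly": float(np.mean(poly_prot)) if poly_prot else None,
            "mean_mono": float(np.mean(mono_prot)) if mono_prot else None,
            "test": safe_test(poly_prot, mono_prot),
        },
        "adjacent_distance": {
            "mean_poly": float(np.mean(poly_gaps)) if poly_gaps else None,
            "mean_other": float(np.mean(other_gaps)) if other_gaps else None,
            "test": safe_test(poly_gaps, other_gaps),
        },
        "stop_codons": {
            "poly": stop_codon_usage(ann, genome, sorted(members)) if members else None,
            "mono": stop_codon_usage(ann, genome, mono) if mono else None,
        },
        "frames": {
            "n_pairs": len(frames),
            "n_in_frame": n_in_frame,
            "in_frame_fraction": n_in_frame / len(frames) if frames else None,
        },
    }


def pcg_total_from_breakdown(breakdown: dict[int, int]) -> int:
    """Total PCGs across loci from a members -> locus-count breakdown."""
    return sum(k * n for k, n in breakdown.items())
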