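"""Overlapping-gene detection and characterization.

Two genes overlap when their transcribed regions (union span of each gene's
mRNA exon chains, UTRs included) share at least one base. Pairs are labelled
by strand relation (same / opposite) and geometry: ``nested`` when one span
contains the other, ``three_prime`` / ``five_prime`` when both genes overlap
at the corresponding transcriptional terminus, ``mixed`` otherwise.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import Annotation, GenomeSequence, Interval
from .stats import welch_t_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapPair:
    gene_a: str
    gene_b: str
    overlap: Interval
    strand_relation: str  # 'same' | 'opposite'
    geometry: str  # 'three_prime' | 'five_prime' | 'nested' | 'mixed'
    fraction_a: float  # overlap bp / transcribed length of gene_a
    fraction_b: float

    @property
    def overlap_bp(self) -> int:
        return len(self.overlap)


def _terminus(strand: str, span: tuple[int, int], ov: tuple[int, int]) -> str | None:
    """Which transcriptional end of a gene the overlap touches, if any."""
    s, e = span
    os_, oe = ov
    at_right = oe == e
    at_left = os_ == s
    if at_left and at_right:
        return "both"
    if at_right:
        return "three_prime" if strand == "+" else "five_prime"
    if at_left:
        return "five_prime" if strand == "+" else "three_prime"
    return None


def find_overlap_pairs(ann: Annotation) -> list[OverlapPair]:
    """Every unordered pair of distinct genes whose transcribed spans share
    at least 1 bp; a gene may appear in several pairs."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    genes = ann.sorted_genes()
    for g in genes:
        s, e = g.span
        trees[g.chrom].addi(s, e, g.gene_id)
    pairs: list[OverlapPair] = []
    seen: set[tuple[str, str]] = set()
    for g in genes:
        s, e = g.span
        for hit in trees[g.chrom].overlap(s, e):
            other_id = hit.data
            if other_id == g.gene_id:
                continue
            key = tuple(sorted((g.gene_id, other_id)))
            if key in seen:
                continue
            seen.add(key)
            a, b = ann[key[0]], ann[key[1]]
            pairs.append(_make_pair(a, b))
    pairs.sort(key=lambda p: (p.overlap.chrom, p.overlap.start, p.gene_a, p.gene_b))
    return pairs


def _make_pair(a, b) -> OverlapPair:
    (sa, ea), (sb, eb) = a.span, b.span
    os_, oe = max(sa, sb), min(ea, eb)
    ov = (os_, oe)
    frac_a = (oe - os_) / (ea - sa)
    frac_b = (oe - os_) / (eb - sb)
    relation = "same" if a.strand == b.strand else "opposite"
    if math.isclose(frac_a, 1.0) or math.isclose(frac_b, 1.0):
        geometry = "nested"
    else:
        ta = _terminus(a.strand, (sa, ea), ov)
        tb = _terminus(b.strand, (sb, eb), ov)
        if ta == tb == "three_prime":
            geometry = "three_prime"
        elif ta == tb == "five_prime":
            geometry = "five_prime"
        else:
            geometry = "mixed"
    return OverlapPair(
        gene_a=a.gene_id, gene_b=b.gene_id,
        overlap=Interval(a.chrom, os_, oe),
        strand_relation=relation, geometry=geometry,
        fraction_a=frac_a, fraction_b=frac_b,
    )


@dataclass
class OverlapSummary:
    n_pairs: int
    n_genes_involved: int
    n_opposite: int
    pct_opposite: float
    n_genes_multi_partner: int
    pct_three_prime: float
    mean_fraction: float
    n_nested_opposite: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_overlaps(pairs: Sequence[OverlapPair]) -> OverlapSummary:
    if not pairs:
        return OverlapSummary(0, 0, 0, 0.0, 0, 0.0, 0.0, 0)
    n_pairs = len(pairs)
    partner_counts: dict[str, int] = defaultdict(int)
    for p in pairs:
        partner_counts[p.gene_a] += 1
        partner_counts[p.gene_b] += 1
    n_opposite = sum(1 for p in pairs if p.strand_relation == "opposite")
    n_three = sum(1 for p in pairs if p.geometry == "three_prime")
    fractions = [f for p in pairs for f in (p.fraction_a, p.fraction_b)]
    return OverlapSummary(
        n_pairs=n_pairs,
        n_genes_involved=len(partner_counts),
        n_opposite=n_opposite,
        pct_opposite=100.0 * n_opposite / n_pairs,
        n_genes_multi_partner=sum(1 for n in partner_counts.values() if n >= 2),
        pct_three_prime=100.0 * n_three / n_pairs,
        mean_fraction=float(np.mean(fractions)),
        n_nested_opposite=sum(
            1 for p in pairs
            if p.geometry == "nested" and p.strand_relation == "opposite"
        ),
    )


def opposite_direction_percent(n_opposite: int, n_pairs: int) -> float:
    """Share of overlap pairs transcribed in opposite directions."""
    return 100.0 * n_opposite / n_pairs


def gc_percent(genome: GenomeSequence, intervals: Sequence[Interval]) -> list[float]:
    """GC% per interval: 100 * (G+C) / (A+C+G+T); N excluded from the
    denominator. All-N intervals are excluded (logged), yielding NaN."""
    if not intervals:
        raise ValueError("empty interval list")
    out: list[float] = []
    n_undef = 0
    for iv in intervals:
        seq = genome.fetch(iv.chrom, iv.start, iv.end)
        gc = seq.count("G") + seq.count("C")
        denom = len(seq) - seq.count("N")
        if denom == 0:
            n_undef += 1
            out.append(float("nan"))
        else:
            out.append(100.0 * gc / denom)
    if n_undef:
        logger.warning("%d all-N intervals excluded from GC computation", n_undef)
    return out


def compare_gc(
    overlap_regions: Sequence[Interval],
    genic_regions: Sequence[Interval],
    genome: GenomeSequence,
) -> dict:
    """Welch two-sided t-test on per-region GC percentages.

    The genic baseline is one value per gene's transcribed span; the overlap
    population is one value per overlapped region.
    """
    a = [v for v in gc_percent(genome, overlap_regions) if not math.isnan(v)]
    b = [v for v in gc_percent(genome, genic_regions) if not math.isnan(v)]
    res = welch_t_test(a, b)
    return {
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "t_statistic": res["t"],
        "p_value": res["p"],
        "p_text": res["p_text"],
    }
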