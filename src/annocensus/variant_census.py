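"""Variant classification and density census.

Variants are classified as SNP, indel (net length change under 50 bp) or SV
(50 bp and over). Densities are reported per 100 bp of genic, coding and
non-genic space; a variant counts toward every region class its reference
footprint overlaps, so boundary-straddling variants appear in more than one
class.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import Annotation, GenomeSequence, VariantRecord, merge_intervals

SV_MIN_LENGTH = 50  # bp of net length change separating indels from SVs


def classify_variant(ref: str, alt: str) -> tuple[str, bool]:
    """Classify one REF->ALT allele pair; returns (class, flagged).

    SNP when both alleles are single bases; otherwise the net length change
    decides indel (< 50 bp) vs SV (>= 50 bp). Balanced multi-base
    substitutions (equal lengths > 1) carry no net length change and are
    flagged, binned by allele length. Symbolic ALT alleles (e.g. ``<DEL>``)
    are SVs, flagged because their true size is not encoded in the alleles.
    """
    if not ref or not alt:
        raise ValueError("empty allele string")
    if alt.startswith("<"):
        return "SV", True
    if len(ref) == 1 and len(alt) == 1:
        return "SNP", False
    size = abs(len(ref) - len(alt))
    if size == 0:  # balanced MNP
        return ("SV", True) if len(ref) >= SV_MIN_LENGTH else ("indel", True)
    return ("SV", False) if size >= SV_MIN_LENGTH else ("indel", False)


@dataclass
class RegionClassMap:
    """Genic (transcribed spans), coding (CDS union) and non-genic intervals
    per chromosome, with total bp per class."""

    genic: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    coding: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    non_genic: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    bp: dict[str, int] = field(default_factory=dict)

    def intervals(self, region_class: str) -> dict[str, list[tuple[int, int]]]:
        return getattr(self, region_class)


def build_region_map(ann: Annotation, genome: GenomeSequence) -> RegionClassMap:
    genic: dict[str, list[tuple[int, int]]] = defaultdict(list)
    coding: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in ann:
        genic[g.chrom].append(g.span)
        coding[g.chrom].extend(g.cds_union())
    rmap = RegionClassMap()
    for chrom, length in genome.lengths.items():
        g_merged = merge_intervals(genic.get(chrom, []))
        rmap.genic[chrom] = g_merged
        rmap.coding[chrom] = merge_intervals(coding.get(chrom, []))
        rmap.non_genic[chrom] = _complement(g_merged, length)
    for cls in ("genic", "coding", "non_genic"):
        rmap.bp[cls] = sum(
            e - s for segs in rmap.intervals(cls).values() for s, e in segs
        )
    return rmap


def _complement(merged: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out, prev = [], 0
    for s, e in merged:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


def region_density(
    variants: Sequence[VariantRecord], region_map: RegionClassMap
) -> dict[str, dict]:
    """Per-class counts, bp, density per 100 bp and variant-class shares.

    A variant is counted in every class its footprint overlaps.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for cls in ("genic", "coding", "non_genic"):
        trees[cls] = {}
        for chrom, segs in region_map.intervals(cls).items():
            t = IntervalTree()
            for s, e in segs:
                if e > s:
                    t.addi(s, e)
            trees[cls][chrom] = t
    out: dict[str, dict] = {}
    for cls in ("genic", "coding", "non_genic"):
        count = 0
        class_shares: dict[str, int] = defaultdict(int)
        for v in variants:
            tree = trees[cls].get(v.chrom)
            if tree is not None and tree.overlaps(v.span.start, v.span.end):
                count += 1
                class_shares[v.var_class] += 1
        bp = region_map.bp[cls]
        out[cls] = {
            "count": count,
            "bp": bp,
            "density_per_100bp": (100.0 * count / bp) if bp else None,
            "by_class": dict(class_shares),
        }
    return out


def class_share_percent(count: int, total: int) -> float:
    """Percentage share of one variant class in a variant set."""
    return 100.0 * count / total


def variant_class_shares(variants: Sequence[VariantRecord]) -> dict[str, dict]:
    """Counts and percentage share per variant class over the whole set."""
    counts: dict[str, int] = defaultdict(int)
    for v in variants:
        counts[v.var_class] += 1
    total = len(variants)
    return {
        cls: {"count": n, "percent": 100.0 * n / total if total else 0.0}
        for cls, n in sorted(counts.items())
    }


def coding_overlap_shift(
    variants: Sequence[VariantRecord],
    annotation_old: Annotation,
    annotation_new: Annotation,
) -> dict[str, int]:
    """How many variants gained or lost coding-region membership between two
    annotations of the same genome."""

    def coding_trees(ann: Annotation) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in ann:
            for s, e in g.cds_union():
                trees[g.chrom].addi(s, e)
        return trees

    t_old, t_new = coding_trees(annotation_old), coding_trees(annotation_new)
    gained = lost = unchanged = 0
    for v in variants:
        in_old = v.chrom in t_old and t_old[v.chrom].overlaps(v.span.start, v.span.end)
        in_new = v.chrom in t_new and t_new[v.chrom].overlaps(v.span.start, v.span.end)
        if in_new and not in_old:
            gained += 1
        elif in_old and not in_new:
            lost += 1
        else:
            unchanged += 1
    return {"n_gained_coding": gained, "n_lost_coding": lost, "unchanged": unchanged}


def per_gene_density(
    variants: Sequence[VariantRecord],
    ann: Annotation,
    conserved_below: float = 10.0,
    variable_above: float = 20.0,
) -> list[dict]:
    """Variant density per gene (per 100 bp of transcribed span) with a
    conserved / intermediate / variable label at the given thresholds."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in ann:
        s, e = g.span
        trees[g.chrom].addi(s, e, g.gene_id)
    counts: dict[str, int] = defaultdict(int)
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(v.span.start, v.span.end):
            counts[hit.data] += 1
    rows = []
    for g in ann.sorted_genes():
        bp = g.span_length
        n = counts.get(g.gene_id, 0)
        density = 100.0 * n / bp
        label = (
            "conserved"
            if density < conserved_below
            else "variable" if density > variable_above else "intermediate"
        )
        rows.append(
            {
                "gene_id": g.gene_id,
                "bp": bp,
                "n_variants": n,
                "density_per_100bp": density,
                "label": label,
            }
        )
    return rows
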