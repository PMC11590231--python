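"""SQANTI-style structural classification of full-length transcripts against
a reference annotation, plus gene/isoform rarefaction curves.

Categories, decided in order for each transcript:

* multi-exon — **FSM** (junction chain equals a reference mRNA's full chain),
  **ISM** (contiguous sub-chain of one), **NIC** (all splice sites known in
  the associated gene's catalog but combined in a new way), **NNC** (at least
  one novel splice site);
* mono-exon — FSM/ISM when contained in a reference mRNA's exon (FSM if that
  mRNA is itself mono-exon), else **genic_genomic** when straddling exon and
  intron space;
* positional — **genic_intron** (fully inside an intron), **antisense**
  (overlapping only an opposite-strand gene), **intergenic**.

Junction matching is exact-coordinate by default; a wobble window can be set
but inputs are assumed to be corrected/collapsed transcript models.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .model import Annotation, TranscriptModel

CATEGORIES = (
    "FSM", "ISM", "NIC", "NNC",
    "antisense", "genic_intron", "genic_genomic", "intergenic",
)
_GENIC = ("FSM", "ISM", "NIC", "NNC")


@dataclass(frozen=True)
class IsoformRecord:
    read_id: str
    category: str
    associated_gene: str | None = None
    associated_ref_mrna: str | None = None
    flagged: bool = False
    isoform_key: Hashable = None  # (gene, junction chain) or mono-exon footprint


class ReferenceIndex:
    """Catalogs a reference annotation for classification: per-gene junction
    chains, splice-site sets and exon unions, plus span trees per strand."""

    def __init__(self, ann: Annotation, wobble: int = 0):
        if wobble != 0:
            raise NotImplementedError("junction wobble windows are not supported yet")
        self.ann = ann
        self.span_trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self.chains: dict[tuple[str, str], dict[tuple, tuple[str, str]]] = defaultdict(dict)
        self.gene_chains: dict[str, list[tuple[str, tuple]]] = defaultdict(list)
        self.gene_junctions: dict[str, set[tuple[int, int]]] = defaultdict(set)
        self.gene_donors: dict[str, set[int]] = defaultdict(set)
        self.gene_acceptors: dict[str, set[int]] = defaultdict(set)
        self.gene_exons: dict[str, list[tuple[int, int]]] = {}
        for g in ann:
            s, e = g.span
            self.span_trees[(g.chrom, g.strand)].addi(s, e, g.gene_id)
            self.gene_exons[g.gene_id] = g.exon_union()
            for m in g.mrnas:
                chain = m.junction_chain()
                if chain:
                    self.chains[(g.chrom, g.strand)].setdefault(
                        chain, (g.gene_id, m.mrna_id)
                    )
                self.gene_chains[g.gene_id].append((m.mrna_id, chain))
                for js, je in chain:
                    self.gene_junctions[g.gene_id].add((js, je))
                    donor, acceptor = (js, je) if g.strand == "+" else (je, js)
                    self.gene_donors[g.gene_id].add(donor)
                    self.gene_acceptors[g.gene_id].add(acceptor)

    def overlapping_genes(self, t: TranscriptModel, strand: str) -> list[str]:
        tree = self.span_trees.get((t.chrom, strand))
        if tree is None:
            return []
        s, e = t.span
        return sorted(hit.data for hit in tree.overlap(s, e))


def _is_subchain(sub: tuple, full: tuple) -> bool:
    n, m = len(sub), len(full)
    if n == 0 or n > m:
        return False
    return any(full[i : i + n] == sub for i in range(m - n + 1))


def _exonic_overlap_bp(exons: Sequence[tuple[int, int]], ref: Sequence[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in exons:
        for s2, e2 in ref:
            lo, hi = max(s1, s2), min(e1, e2)
            if hi > lo:
                total += hi - lo
    return total


def classify_isoform(
    transcript: TranscriptModel, index: ReferenceIndex
) -> IsoformRecord:
    """Assign one structural category; see module docstring for the order."""
    t = transcript
    opposite = {"+": "-", "-": "+"}.get(t.strand)
    same_genes = index.overlapping_genes(t, t.strand) if t.stranded else []
    chain = t.junction_chain()

    if chain:  # multi-exon
        hit = index.chains.get((t.chrom, t.strand), {}).get(chain)
        if hit is not None:
            return _rec(t, "FSM", hit[0], hit[1], chain=chain)
        for gid in same_genes:
            for mrna_id, full in index.gene_chains[gid]:
                if _is_subchain(chain, full):
                    return _rec(t, "ISM", gid, mrna_id, chain=chain)
        exonic = [
            (gid, _exonic_overlap_bp(t.exons, index.gene_exons[gid]))
            for gid in same_genes
        ]
        exonic = [(gid, bp) for gid, bp in exonic if bp > 0]
        if exonic:
            best_bp = max(bp for _, bp in exonic)
            tied = sorted(gid for gid, bp in exonic if bp == best_bp)
            gid, flagged = tied[0], len(tied) > 1
            known = index.gene_junctions[gid]
            donors = index.gene_donors[gid]
            acceptors = index.gene_acceptors[gid]
            novel = False
            for js, je in chain:
                if (js, je) in known:
                    continue
                d, a = (js, je) if t.strand == "+" else (je, js)
                if d not in donors or a not in acceptors:
                    novel = True
                    break
            cat = "NNC" if novel else "NIC"
            return _rec(t, cat, gid, flagged=flagged, chain=chain)
        if same_genes:  # span overlap but no exonic overlap: inside an intron
            return _rec(t, "genic_intron", associated=None)
        if opposite and index.overlapping_genes(t, opposite):
            return _rec(t, "antisense")
        return _rec(t, "intergenic")

    # mono-exon
    s, e = t.exons[0]
    for gid in same_genes:
        for m in index.ann[gid].mrnas:
            for es, ee in m.exons:
                if es <= s and e <= ee:
                    cat = "FSM" if len(m.exons) == 1 else "ISM"
                    return _rec(t, cat, gid, m.mrna_id, mono_span=(s, e))
    exonic = [
        gid for gid in same_genes
        if _exonic_overlap_bp(t.exons, index.gene_exons[gid]) > 0
    ]
    if exonic:
        return _rec(t, "genic_genomic")
    if same_genes:
        return _rec(t, "genic_intron")
    if opposite and t.stranded and index.overlapping_genes(t, opposite):
        return _rec(t, "antisense")
    return _rec(t, "intergenic")


def _rec(
    t: TranscriptModel,
    category: str,
    associated: str | None = None,
    mrna: str | None = None,
    flagged: bool = False,
    chain: tuple | None = None,
    mono_span: tuple | None = None,
) -> IsoformRecord:
    key = None
    if associated is not None:
        key = (associated, chain) if chain else (associated, "mono", mono_span)
    return IsoformRecord(
        read_id=t.read_id, category=category, associated_gene=associated,
        associated_ref_mrna=mrna, flagged=flagged, isoform_key=key,
    )


def classify_all(
    transcripts: Iterable[TranscriptModel], ann: Annotation, wobble: int = 0
) -> list[IsoformRecord]:
    index = ReferenceIndex(ann, wobble=wobble)
    return [classify_isoform(t, index) for t in transcripts if t.stranded]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def classification_summary(records: Sequence[IsoformRecord]) -> dict:
    """Category counts/percentages plus the alternative-splicing summary.

    A unique isoform is a distinct junction chain per associated gene
    (mono-exon reads: a distinct exonic footprint). A gene with two or more
    unique isoforms counts as alternatively spliced."""
    counts = Counter(r.category for r in records)
    total = len(records)
    per_gene: dict[str, set] = defaultdict(set)
    for r in records:
        if r.associated_gene is not None and r.category in _GENIC:
            per_gene[r.associated_gene].add(r.isoform_key)
    iso_counts = {g: len(keys) for g, keys in per_gene.items()}
    n_genes = len(iso_counts)
    n_2plus = sum(1 for n in iso_counts.values() if n >= 2)
    n_10plus = sum(1 for n in iso_counts.values() if n > 10)
    total_isoforms = sum(iso_counts.values())
    return {
        "categories": {
            c: {"count": counts.get(c, 0),
                "percent": 100.0 * counts.get(c, 0) / total if total else 0.0}
            for c in CATEGORIES
        },
        "n_records": total,
        "n_flagged": sum(1 for r in records if r.flagged),
        "per_gene_isoforms": iso_counts,
        "as_summary": {
            "n_genes": n_genes,
            "n_isoforms": total_isoforms,
            "n_no_AS": n_genes - n_2plus,
            "n_2plus": n_2plus,
            "n_10plus": n_10plus,
            "pct_AS": pct_as(n_2plus, n_genes) if n_genes else 0.0,
            "mean_isoforms_per_gene": (
                mean_isoforms_per_gene(total_isoforms, n_genes) if n_genes else 0.0
            ),
        },
    }


def pct_as(n_2plus: int, n_genes: int) -> float:
    """Percent of expressed genes with two or more splice isoforms."""
    return 100.0 * n_2plus / n_genes


def mean_isoforms_per_gene(n_isoforms: int, n_genes: int) -> float:
    """Genome-wide alternative-splicing rate: isoforms per expressed gene."""
    return n_isoforms / n_genes


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

@dataclass
class RarefactionCurve:
    sample_sizes: list[int]
    mean_genes: list[float]
    sd_genes: list[float]
    mean_isoforms: list[float]
    sd_isoforms: list[float]
    replicates: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sample_sizes,
                "mean_genes": self.mean_genes,
                "sd_genes": self.sd_genes,
                "mean_isoforms": self.mean_isoforms,
                "sd_isoforms": self.sd_isoforms,
            }
        )


def rarefaction(
    records: Sequence[IsoformRecord],
    sample_sizes: Sequence[int],
    replicates: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Subsample reads without replacement and count distinct genes and
    unique isoforms discovered; deterministic for a fixed seed."""
    n = len(records)
    sizes = sorted(sample_sizes)
    if sizes and sizes[-1] > n:
        raise ValueError(f"sample size {sizes[-1]} exceeds population {n}")
    genes = np.empty(n, dtype=object)
    keys = np.empty(n, dtype=object)
    for i, r in enumerate(records):
        genes[i] = r.associated_gene or ""
        keys[i] = r.isoform_key  # tuples; kept opaque inside an object array
    rng = np.random.default_rng(seed)
    mg, sg, mi, si = [], [], [], []
    for size in sizes:
        g_counts, i_counts = [], []
        for _ in range(replicates):
            idx = rng.choice(n, size=size, replace=False) if size else np.array([], int)
            g_counts.append(len({g for g in genes[idx] if g}))
            i_counts.append(len({k for k in keys[idx] if k is not None}))
        mg.append(float(np.mean(g_counts)))
        sg.append(float(np.std(g_counts)))
        mi.append(float(np.mean(i_counts)))
        si.append(float(np.std(i_counts)))
    return RarefactionCurve(sizes, mg, sg, mi, si, replicates, seed)


def expected_unique(class_counts: Sequence[int], n: int) -> float:
    """Closed-form expected number of distinct classes discovered when
    sampling *n* items without replacement from a population whose class
    sizes are ``class_counts``: sum over classes of
    1 - C(N - c, n) / C(N, n)."""
    N = int(sum(class_counts))
    return float(sum(1.0 - hypergeom.pmf(0, N, c, n) for c in class_counts))
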