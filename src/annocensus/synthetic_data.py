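"""Synthetic genome / annotation / transcript / haplotype simulator with
machine-readable truth tables.

The simulator emulates the statistical structure of a compact fungal genome
annotation: multi-chromosome genome, intron-containing protein-coding genes
(GT-AG introns plus configurable non-canonical types), planted overlapping
gene pairs (convergent 3', divergent 5', nested antisense), tandem same-strand
gene runs with short linkers and readthrough transcripts, per-gene
full-length reads with configurable truncation (ISM) and novel-junction
(NNC) fractions, and a second haplotype carrying SNPs, indels (< 50 bp) and
SVs (>= 50 bp).

Only the bases the gene models constrain are written into the background
sequence: CDS codons and intron boundary dinucleotides. UTRs and intron
interiors keep the random background, which is what lets planted gene spans
overlap without sequence conflicts. Identical config + seed give
byte-identical output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    Annotation,
    GeneModel,
    GenomeSequence,
    MrnaModel,
    TranscriptModel,
    VariantRecord,
    merge_intervals,
    reverse_complement,
)
from . import core_io
from .variant_census import classify_variant

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
]


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults give a desk-scale genome
    (2 x 500 kb, ~300 genes, a few thousand reads) that runs in seconds."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    n_genes: int = 300
    gene_gap_range: tuple[int, int] = (200, 1200)
    exons_per_gene_range: tuple[int, int] = (1, 8)
    codons_per_gene_range: tuple[int, int] = (80, 450)
    intron_length_range: tuple[int, int] = (50, 200)
    utr_length_range: tuple[int, int] = (20, 120)
    gc_content: float = 0.557
    # splice-type fractions among planted introns; remainder is GT-AG
    noncanonical_rates: dict[str, float] = field(
        default_factory=lambda: {"GC-AG": 0.0185, "GT-AC": 0.005, "GT-GG": 0.004,
                                 "AT-AC": 0.003}
    )
    # (geometry, strand_relation) of planted overlap pairs
    overlap_plants: tuple[tuple[str, str], ...] = (
        ("three_prime", "opposite"),) * 8 + (
        ("five_prime", "opposite"),) * 2 + (
        ("nested", "opposite"),) * 2
    # member count of each planted polycistron run
    polycistron_plants: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 2, 3, 3, 4)
    linker_length_range: tuple[int, int] = (100, 400)
    reads_per_gene: float = 12.0
    ism_rate: float = 0.20
    nnc_rate: float = 0.05
    antisense_rate: float = 0.02
    intergenic_rate: float = 0.02
    readthrough_reads_per_locus: int = 3
    snp_per_kb: float = 9.0
    indel_per_kb: float = 1.1
    sv_per_kb: float = 0.05
    genic_bias: float = 1.0  # relative per-bp variant rate genic : non-genic
    stop_codon_distribution: dict[str, float] = field(
        default_factory=lambda: {"TGA": 0.5, "TAA": 0.3, "TAG": 0.2}
    )

    def validate(self) -> None:
        for rate in (self.ism_rate, self.nnc_rate, self.antisense_rate,
                     self.intergenic_rate, *self.noncanonical_rates.values()):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if sum(self.noncanonical_rates.values()) > 1.0:
            raise ValueError("non-canonical rates sum above 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a flat key: value YAML mapping; unknown keys raise."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gene_gap_range", "exons_per_gene_range", "codons_per_gene_range",
                    "intron_length_range", "utr_length_range", "linker_length_range",
                    "polycistron_plants"):
            if key in data:
                data[key] = tuple(data[key])
        if "overlap_plants" in data:
            data["overlap_plants"] = tuple(tuple(x) for x in data["overlap_plants"])
        return cls(**data)


@dataclass
class TruthTables:
    """Ground truth for every planted feature, one record per feature."""

    introns: list[dict] = field(default_factory=list)
    overlap_pairs: list[dict] = field(default_factory=list)
    polycistrons: list[dict] = field(default_factory=list)
    reads: list[dict] = field(default_factory=list)
    variants: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    plain_gene_ids: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        for name in ("introns", "overlap_pairs", "polycistrons", "reads",
                     "variants", "genes"):
            rows = getattr(self, name)
            df = pd.DataFrame(rows)
            df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene structure specs
# ---------------------------------------------------------------------------

@dataclass
class _GeneSpec:
    gene_id: str
    strand: str
    utr5: int
    utr3: int
    cds_pieces: list[int]  # spliced CDS piece lengths, transcription order
    intron_lengths: list[int]
    intron_types: list[str]
    cds_seq: str
    stop_codon: str

    @property
    def genomic_length(self) -> int:
        return self.utr5 + self.utr3 + sum(self.cds_pieces) + sum(self.intron_lengths)


def _draw_splice_type(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    u = rng.random()
    acc = 0.0
    for t, rate in sorted(cfg.noncanonical_rates.items()):
        acc += rate
        if u < acc:
            return t
    return "GT-AG"


def _draw_stop(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    stops = sorted(cfg.stop_codon_distribution)
    probs = np.array([cfg.stop_codon_distribution[s] for s in stops], dtype=float)
    return stops[rng.choice(len(stops), p=probs / probs.sum())]


def _make_gene_spec(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    gene_id: str,
    strand: str,
    n_exons: int | None = None,
    n_codons: int | None = None,
    utr5: int | None = None,
    utr3: int | None = None,
    intron_lengths: list[int] | None = None,
) -> _GeneSpec:
    if n_codons is None:
        n_codons = int(rng.integers(*cfg.codons_per_gene_range))
    cds_len = 3 * n_codons
    if n_exons is None:
        n_exons = int(rng.integers(cfg.exons_per_gene_range[0],
                                   cfg.exons_per_gene_range[1] + 1))
    n_exons = max(1, min(n_exons, cds_len // 40))
    pieces = _split_cds(rng, cds_len, n_exons)
    n_introns = n_exons - 1
    if intron_lengths is None:
        intron_lengths = [
            int(rng.integers(*cfg.intron_length_range)) for _ in range(n_introns)
        ]
    types = [_draw_splice_type(rng, cfg) for _ in range(n_introns)]
    stop = _draw_stop(rng, cfg)
    internal = rng.choice(len(_CODONS), size=n_codons - 2)
    cds_seq = "ATG" + "".join(_CODONS[i] for i in internal) + stop
    lo, hi = cfg.utr_length_range
    return _GeneSpec(
        gene_id=gene_id, strand=strand,
        utr5=utr5 if utr5 is not None else int(rng.integers(lo, hi + 1)),
        utr3=utr3 if utr3 is not None else int(rng.integers(lo, hi + 1)),
        cds_pieces=pieces, intron_lengths=intron_lengths, intron_types=types,
        cds_seq=cds_seq, stop_codon=stop,
    )


def _split_cds(rng: np.random.Generator, cds_len: int, n_exons: int) -> list[int]:
    if n_exons == 1:
        return [cds_len]
    for _ in range(200):
        cuts = np.sort(rng.integers(20, cds_len - 20, size=n_exons - 1))
        bounds = [0, *cuts.tolist(), cds_len]
        pieces = [b - a for a, b in zip(bounds, bounds[1:])]
        if min(pieces) >= 20:
            return pieces
    raise RuntimeError("could not split CDS into exon pieces; CDS too short")


# ---------------------------------------------------------------------------
# Placement and sequence writing
# ---------------------------------------------------------------------------

@dataclass
class _Placed:
    spec: _GeneSpec
    chrom: str
    start: int
    exons: list[tuple[int, int]]  # genomic ascending
    cds: list[tuple[int, int]]
    introns: list[tuple[int, int, str]]  # (start, end, splice_type)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def _layout(spec: _GeneSpec, chrom: str, start: int) -> _Placed:
    """Compute genomic exon/CDS/intron coordinates of a gene placed at
    ``start`` (leftmost genomic base)."""
    # transcription-order element list
    elements: list[tuple[str, int, str | None]] = []
    for i, piece in enumerate(spec.cds_pieces):
        elements.append(("cds", piece, None))
        if i < len(spec.intron_lengths):
            elements.append(("intron", spec.intron_lengths[i], spec.intron_types[i]))
    elements = [("utr", spec.utr5, None), *elements, ("utr", spec.utr3, None)]
    if spec.strand == "-":
        # transcription runs right->left; genomic order is the reverse
        elements = elements[::-1]
    cur = start
    exonic: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    introns: list[tuple[int, int, str]] = []
    for kind, length, stype in elements:
        iv = (cur, cur + length)
        if kind == "intron":
            introns.append((iv[0], iv[1], stype))
        else:
            exonic.append(iv)
            if kind == "cds":
                cds.append(iv)
        cur += length
    return _Placed(
        spec=spec, chrom=chrom, start=start,
        exons=merge_intervals(exonic), cds=sorted(cds), introns=sorted(introns),
    )


def _write_gene(seq: list[str], placed: _Placed) -> None:
    """Write the constrained bases (CDS codons, intron boundary
    dinucleotides) of one placed gene into the chromosome array."""
    spec = placed.spec
    # distribute the spliced CDS over the genomic CDS segments
    segs = placed.cds if spec.strand == "+" else placed.cds[::-1]
    off = 0
    for s, e in segs:
        piece = spec.cds_seq[off : off + (e - s)]
        off += e - s
        if spec.strand == "-":
            piece = reverse_complement(piece)
        seq[s:e] = list(piece)
    intr = placed.introns if spec.strand == "+" else placed.introns[::-1]
    types = spec.intron_types
    for (s, e, _), stype in zip(intr, types):
        donor, acceptor = stype.split("-")
        if spec.strand == "+":
            seq[s : s + 2] = list(donor)
            seq[e - 2 : e] = list(acceptor)
        else:
            seq[e - 2 : e] = list(reverse_complement(donor))
            seq[s : s + 2] = list(reverse_complement(acceptor))


def _to_gene_model(placed: _Placed) -> GeneModel:
    gid = placed.spec.gene_id
    mrna = MrnaModel(
        mrna_id=f"{gid}.t1", exons=placed.exons, cds=placed.cds,
        strand=placed.spec.strand,
    )
    return GeneModel(gene_id=gid, chrom=placed.chrom, strand=placed.spec.strand,
                     mrnas=[mrna])


# ---------------------------------------------------------------------------
# Simulation result container
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: GenomeSequence
    annotation: Annotation
    transcripts: list[TranscriptModel]
    variants: list  # VariantRecord
    haplotype: GenomeSequence | None
    truth: TruthTables

    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gff3",
            "transcripts": outdir / "transcripts.bed",
            "variants": outdir / "variants.vcf",
        }
        core_io.write_genome(self.genome, paths["genome"])
        core_io.write_annotation(self.annotation, paths["annotation"])
        core_io.write_transcripts(self.transcripts, paths["transcripts"])
        core_io.write_variants(self.variants, paths["variants"],
                               contig_lengths=self.genome.lengths)
        if self.haplotype is not None:
            paths["haplotype"] = outdir / "haplotype.fa"
            core_io.write_genome(self.haplotype, paths["haplotype"])
        self.truth.write(outdir)
        return paths


# ---------------------------------------------------------------------------
# Stage 1: genome + annotation
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, Annotation, TruthTables]:
    """Build the genome FASTA / annotation GFF3 content with planted gene
    structures, overlap pairs and polycistron runs; deterministic for a
    fixed config (the seed lives in the config)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    truth = TruthTables()
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    n_special = 2 * len(config.overlap_plants) + sum(config.polycistron_plants)
    n_plain = config.n_genes - n_special
    if n_plain < 0:
        raise ValueError(
            "n_genes smaller than the genes consumed by planted overlap pairs "
            "and polycistron runs; raise n_genes or trim the plant lists"
        )

    serial = itertools.count(1)

    def next_id() -> str:
        return f"g{next(serial):05d}"

    # --- plan placement units -------------------------------------------
    units: list[dict] = []
    for geometry, relation in config.overlap_plants:
        units.append(_plan_overlap_pair(rng, config, geometry, relation, next_id))
    for k in config.polycistron_plants:
        units.append(_plan_polycistron_run(rng, config, k, next_id))
    for _ in range(n_plain):
        strand = "+" if rng.random() < 0.5 else "-"
        spec = _make_gene_spec(rng, config, next_id(), strand)
        units.append({"kind": "plain", "specs": [(spec, 0)],
                      "length": spec.genomic_length})
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    # --- background sequence --------------------------------------------
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    seqs: dict[str, list[str]] = {
        c: alphabet[rng.choice(4, size=config.chromosome_length, p=probs)].tolist()
        for c in chroms
    }

    # --- pack units onto chromosomes ------------------------------------
    ann = Annotation()
    margin = 300
    chrom_iter = iter(chroms)
    chrom = next(chrom_iter)
    cursor = margin
    for unit in units:
        gap = int(rng.integers(*config.gene_gap_range))
        while cursor + gap + unit["length"] > config.chromosome_length - margin:
            nxt = next(chrom_iter, None)
            if nxt is None:
                raise ValueError(
                    "infeasible packing: planted genes exceed genome capacity; "
                    "increase chromosome_length / n_chromosomes or lower n_genes"
                )
            chrom, cursor = nxt, margin
        start = cursor + gap
        placed_list = []
        for spec, offset in unit["specs"]:
            placed = _layout(spec, chrom, start + offset)
            _write_gene(seqs[chrom], placed)
            ann.add(_to_gene_model(placed))
            placed_list.append(placed)
            _record_gene_truth(truth, placed)
        _record_unit_truth(truth, unit, placed_list)
        cursor = start + unit["length"]

    genome = GenomeSequence({c: "".join(seqs[c]) for c in chroms})
    return genome, ann, truth


def _record_gene_truth(truth: TruthTables, placed: _Placed) -> None:
    spec = placed.spec
    truth.genes.append(
        {
            "gene_id": spec.gene_id, "chrom": placed.chrom,
            "strand": spec.strand, "start": placed.span[0], "end": placed.span[1],
            "stop_codon": spec.stop_codon, "n_introns": len(placed.introns),
        }
    )
    for s, e, stype in placed.introns:
        truth.introns.append(
            {
                "chrom": placed.chrom, "start": s, "end": e,
                "strand": spec.strand, "gene_id": spec.gene_id,
                "splice_type": stype,
            }
        )


def _record_unit_truth(truth: TruthTables, unit: dict, placed: list[_Placed]) -> None:
    if unit["kind"] == "plain":
        truth.plain_gene_ids.append(placed[0].spec.gene_id)
    elif unit["kind"] == "overlap":
        a, b = placed
        truth.overlap_pairs.append(
            {
                "gene_a": min(a.spec.gene_id, b.spec.gene_id),
                "gene_b": max(a.spec.gene_id, b.spec.gene_id),
                "geometry": unit["geometry"],
                "strand_relation": unit["relation"],
            }
        )
    elif unit["kind"] == "polycistron":
        members = [p.spec.gene_id for p in placed]
        strand = placed[0].spec.strand
        if strand == "-":
            members = members[::-1]  # transcription order
        # readthrough exon chain: run span minus all member introns
        span = (min(p.span[0] for p in placed), max(p.span[1] for p in placed))
        introns = sorted((s, e) for p in placed for s, e, _ in p.introns)
        exons, prev = [], span[0]
        for s, e in introns:
            exons.append((prev, s))
            prev = e
        exons.append((prev, span[1]))
        truth.polycistrons.append(
            {
                "members": ",".join(members),
                "n_members": len(members),
                "chrom": placed[0].chrom,
                "strand": strand,
                "linker_lengths": ",".join(str(x) for x in unit["linkers"]),
                "frames": ",".join(str(x % 3) for x in unit["linkers"]),
                "readthrough_exons": ";".join(f"{s}-{e}" for s, e in exons),
            }
        )


def _plan_overlap_pair(rng, cfg, geometry, relation, next_id) -> dict:
    if relation != "opposite":
        raise ValueError("only opposite-strand overlap plants are supported")
    if geometry == "nested":
        inner = _make_gene_spec(rng, cfg, next_id(), "-", n_exons=1,
                                n_codons=int(rng.integers(30, 60)),
                                utr5=10, utr3=10)
        margin = 15
        intron_len = inner.genomic_length + 2 * margin
        outer = _make_gene_spec(rng, cfg, next_id(), "+", n_exons=2,
                                intron_lengths=[intron_len])
        # outer is '+', so its single intron starts after utr5 + first piece
        inner_off = outer.utr5 + outer.cds_pieces[0] + margin
        return {"kind": "overlap", "geometry": geometry, "relation": relation,
                "specs": [(outer, 0), (inner, inner_off)],
                "length": outer.genomic_length}
    overlap = int(rng.integers(30, 120))
    ext = overlap + int(rng.integers(10, 50))
    if geometry == "three_prime":
        a = _make_gene_spec(rng, cfg, next_id(), "+", utr3=ext)
        b = _make_gene_spec(rng, cfg, next_id(), "-", utr3=ext)
    elif geometry == "five_prime":
        a = _make_gene_spec(rng, cfg, next_id(), "-", utr5=ext)
        b = _make_gene_spec(rng, cfg, next_id(), "+", utr5=ext)
    else:
        raise ValueError(f"unknown overlap geometry {geometry!r}")
    b_off = a.genomic_length - overlap
    return {"kind": "overlap", "geometry": geometry, "relation": relation,
            "specs": [(a, 0), (b, b_off)],
            "length": b_off + b.genomic_length}


def _plan_polycistron_run(rng, cfg, k, next_id) -> dict:
    strand = "+" if rng.random() < 0.5 else "-"
    # specs in genomic (left-to-right) order; on '-' the first transcribed
    # gene sits rightmost
    specs = [
        _make_gene_spec(rng, cfg, next_id(), strand,
                        utr5=int(rng.integers(20, 40)),
                        utr3=int(rng.integers(20, 40)))
        for _ in range(k)
    ]
    offsets, linkers_genomic = [0], []
    for left, right in zip(specs, specs[1:]):
        # linker = upstream CDS end -> downstream CDS start; genomically it is
        # the two facing UTRs plus the span gap between the genes
        target = int(rng.integers(*cfg.linker_length_range))
        pad = (left.utr3 + right.utr5) if strand == "+" else (right.utr3 + left.utr5)
        gap = max(target - pad, 20)
        linkers_genomic.append(pad + gap)
        offsets.append(offsets[-1] + left.genomic_length + gap)
    length = offsets[-1] + specs[-1].genomic_length
    linkers_tx = linkers_genomic if strand == "+" else linkers_genomic[::-1]
    return {"kind": "polycistron", "specs": list(zip(specs, offsets)),
            "length": length, "linkers": linkers_tx}


# ---------------------------------------------------------------------------
# Stage 2: transcripts
# ---------------------------------------------------------------------------

def simulate_transcripts(
    genome: GenomeSequence,
    ann: Annotation,
    config: SimulationConfig,
    truth: TruthTables,
) -> list[TranscriptModel]:
    """Per-gene full-length reads (FSM, with configured ISM / NNC fractions),
    readthrough reads over planted polycistron runs, and antisense /
    intergenic background reads. Truth labels go into ``truth.reads``."""
    rng = np.random.default_rng([config.seed, 2])
    reads: list[TranscriptModel] = []
    counter = itertools.count(1)

    def rid() -> str:
        return f"read{next(counter):06d}"

    n_gene_reads = 0
    for gene in ann.sorted_genes():
        mrna = gene.representative_mrna()
        n = max(1, int(rng.poisson(config.reads_per_gene)))
        n_gene_reads += n
        for _ in range(n):
            u = rng.random()
            exons = list(mrna.exons)
            category = "FSM"
            if u < config.ism_rate and len(exons) >= 2:
                k = int(rng.integers(1, len(exons)))
                exons = exons[k:] if gene.strand == "+" else exons[:-k]
                category = "ISM"
            elif u < config.ism_rate + config.nnc_rate and len(exons) >= 2:
                exons, ok = _shift_donor(exons, gene.strand, rng)
                category = "NNC" if ok else "FSM"
            reads.append(TranscriptModel(rid(), gene.chrom, gene.strand, exons))
            truth.reads.append(
                {"read_id": reads[-1].read_id, "category": category,
                 "gene_id": gene.gene_id}
            )

    for row in truth.polycistrons:
        exons = [
            tuple(int(x) for x in part.split("-"))
            for part in row["readthrough_exons"].split(";")
        ]
        for _ in range(config.readthrough_reads_per_locus):
            reads.append(TranscriptModel(rid(), row["chrom"], row["strand"], exons))
            truth.reads.append(
                {"read_id": reads[-1].read_id, "category": "readthrough",
                 "gene_id": row["members"]}
            )

    plain = [gid for gid in truth.plain_gene_ids]
    n_anti = int(round(config.antisense_rate * n_gene_reads))
    for _ in range(n_anti):
        gid = plain[int(rng.integers(len(plain)))]
        g = ann[gid]
        s, e = g.span
        length = min(200, e - s - 2)
        pos = int(rng.integers(s, e - length))
        strand = "-" if g.strand == "+" else "+"
        reads.append(TranscriptModel(rid(), g.chrom, strand, [(pos, pos + length)]))
        truth.reads.append(
            {"read_id": reads[-1].read_id, "category": "antisense", "gene_id": gid}
        )

    n_inter = int(round(config.intergenic_rate * n_gene_reads))
    deserts = _intergenic_deserts(genome, ann, margin=500)
    if not deserts:
        n_inter = 0
    for _ in range(n_inter):
        chrom, s, e = deserts[int(rng.integers(len(deserts)))]
        length = min(300, e - s - 2)
        pos = int(rng.integers(s, e - length))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(TranscriptModel(rid(), chrom, strand, [(pos, pos + length)]))
        truth.reads.append(
            {"read_id": reads[-1].read_id, "category": "intergenic", "gene_id": ""}
        )
    return reads


def _shift_donor(exons, strand, rng) -> tuple[list[tuple[int, int]], bool]:
    """Move one donor 4 bp into its exon, creating a novel splice site."""
    exons = list(exons)
    j = int(rng.integers(len(exons) - 1))
    if strand == "+":
        s, e = exons[j]
        if e - s <= 24:
            return exons, False
        exons[j] = (s, e - 4)
    else:
        s, e = exons[j + 1]
        if e - s <= 24:
            return exons, False
        exons[j + 1] = (s + 4, e)
    return exons, True


def _intergenic_deserts(genome, ann, margin=500) -> list[tuple[str, int, int]]:
    spans = {c: [] for c in genome.lengths}
    for g in ann:
        s, e = g.span
        spans[g.chrom].append((max(0, s - margin), e + margin))
    out = []
    for chrom, length in genome.lengths.items():
        prev = 0
        for s, e in merge_intervals(spans[chrom]):
            if s - prev >= 400:
                out.append((chrom, prev, s))
            prev = max(prev, e)
        if length - prev >= 400:
            out.append((chrom, prev, length))
    return out


# ---------------------------------------------------------------------------
# Stage 3: haplotype / variants
# ---------------------------------------------------------------------------

def simulate_haplotype(
    genome: GenomeSequence,
    ann: Annotation,
    config: SimulationConfig,
    truth: TruthTables,
):
    """Plant SNPs, indels (1-49 bp) and SVs (50+ bp) at the configured per-kb
    densities on a second haplotype; VCF coordinates refer to the original
    genome. ``genic_bias`` > 1 concentrates variants into genic space."""
    rng = np.random.default_rng([config.seed, 3])
    total_bp = genome.total_length()
    genic: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.lengths}
    coding: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.lengths}
    for g in ann:
        genic[g.chrom].append(g.span)
        coding[g.chrom].extend(g.cds_union())
    genic = {c: merge_intervals(v) for c, v in genic.items()}
    coding = {c: merge_intervals(v) for c, v in coding.items()}
    non_genic = {
        c: _complement_intervals(genic[c], genome.lengths[c]) for c in genome.lengths
    }

    def flat(segs_by_chrom):
        return [(c, s, e) for c in sorted(segs_by_chrom) for s, e in segs_by_chrom[c]]

    genic_flat, non_flat = flat(genic), flat(non_genic)
    genic_bp = sum(e - s for _, s, e in genic_flat)
    non_bp = sum(e - s for _, s, e in non_flat)
    p_genic = config.genic_bias * genic_bp / (config.genic_bias * genic_bp + non_bp)

    counts = {
        "SNP": int(round(config.snp_per_kb * total_bp / 1000)),
        "indel": int(round(config.indel_per_kb * total_bp / 1000)),
        "SV": int(round(config.sv_per_kb * total_bp / 1000)),
    }
    occupied: dict[str, set[int]] = {c: set() for c in genome.lengths}
    variants = []
    bases = "ACGT"
    for var_class in ("SV", "indel", "SNP"):  # big footprints first
        for _ in range(counts[var_class]):
            placed = False
            for _attempt in range(200):
                segs = genic_flat if rng.random() < p_genic else non_flat
                chrom, s, e = segs[int(rng.integers(len(segs)))]
                if var_class == "SNP":
                    size, footprint = 0, 1
                elif var_class == "indel":
                    size = int(rng.integers(1, 50))
                    footprint = size + 1
                else:
                    size = int(rng.integers(50, 250))
                    footprint = size + 1
                if e - s <= footprint + 2:
                    continue
                pos = int(rng.integers(s, e - footprint - 1))
                cells = range(pos, pos + footprint + 1)
                if any(p in occupied[chrom] for p in cells):
                    continue
                occupied[chrom].update(cells)
                ref_base = genome.sequences[chrom][pos]
                if var_class == "SNP":
                    alt = bases[int(rng.integers(4))]
                    while alt == ref_base:
                        alt = bases[int(rng.integers(4))]
                    ref = ref_base
                elif rng.random() < 0.5:  # deletion
                    ref = genome.sequences[chrom][pos : pos + size + 1]
                    alt = ref_base
                else:  # insertion
                    ins = "".join(bases[i] for i in rng.integers(0, 4, size))
                    ref = ref_base
                    alt = ref_base + ins
                cls, flagged = classify_variant(ref, alt)
                v = VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                  var_class=cls, variant_id=f"var{len(variants)+1:06d}",
                                  flagged=flagged)
                variants.append(v)
                truth.variants.append(
                    {
                        "variant_id": v.variant_id, "chrom": chrom, "pos": pos,
                        "var_class": var_class,
                        "genic": _hits(genic[chrom], pos, pos + max(1, len(ref))),
                        "coding": _hits(coding[chrom], pos, pos + max(1, len(ref))),
                        "non_genic": _hits(non_genic[chrom], pos, pos + max(1, len(ref))),
                    }
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    "could not place a variant without overlap after 200 tries; "
                    "lower the variant densities"
                )
    variants.sort(key=lambda v: (v.chrom, v.pos))

    hap = {}
    for chrom, seq in genome.sequences.items():
        edits = sorted(
            (v for v in variants if v.chrom == chrom),
            key=lambda v: v.pos, reverse=True,
        )
        s = seq
        for v in edits:
            s = s[: v.pos] + v.alt + s[v.pos + len(v.ref):]
        hap[chrom] = s
    return variants, GenomeSequence(hap)


def _complement_intervals(merged, length):
    out, prev = [], 0
    for s, e in merged:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


def _hits(segs: Sequence[tuple[int, int]], s: int, e: int) -> bool:
    return any(min(e, ce) > max(s, cs) for cs, ce in segs)


# ---------------------------------------------------------------------------
# One-call pipeline
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig | None = None) -> SimulationResult:
    config = config or SimulationConfig()
    genome, ann, truth = simulate_genome(config)
    transcripts = simulate_transcripts(genome, ann, config, truth)
    variants, hap = simulate_haplotype(genome, ann, config, truth)
    return SimulationResult(
        config=config, genome=genome, annotation=ann,
        transcripts=transcripts, variants=variants, haplotype=hap, truth=truth,
    )
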