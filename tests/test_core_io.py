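"""Format readers/writers, interval algebra, and annotation diffing."""

import numpy as np
import pytest

from annocensus import core_io
from annocensus.model import Annotation, Interval
from conftest import make_annotation, make_gene


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestReadGenome:
    def test_two_records(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n>chr2\nGGGG\n")
        g = core_io.read_genome(p)
        assert g.lengths == {"chr1": 4, "chr2": 4}

    def test_lowercase_and_u_mapped(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nacgu\n")
        assert core_io.read_genome(p).sequences["c"] == "ACGT"

    def test_ambiguity_codes_become_n(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nACRT\n")
        assert core_io.read_genome(p).sequences["c"] == "ACNT"

    def test_duplicate_id_raises(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nAAAA\n>c\nCCCC\n")
        with pytest.raises(ValueError, match="duplicate"):
            core_io.read_genome(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            core_io.read_genome(p)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

GFF = """##gff-version 3
chr1\tx\tgene\t1\t300\t.\t{strand}\t.\tID=g1
chr1\tx\tmRNA\t1\t300\t.\t{strand}\t.\tID=g1.t1;Parent=g1
chr1\tx\texon\t1\t100\t.\t{strand}\t.\tID=e1;Parent=g1.t1
chr1\tx\texon\t201\t300\t.\t{strand}\t.\tID=e2;Parent=g1.t1
chr1\tx\tCDS\t1\t100\t.\t{strand}\t0\tID=c1;Parent=g1.t1
"""


class TestGff3:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_coordinate_conversion_and_order(self, tmp_path, strand):
        p = tmp_path / "a.gff3"
        p.write_text(GFF.format(strand=strand))
        ann = core_io.read_annotation(p)
        m = ann["g1"].mrnas[0]
        # 1-based closed -> 0-based half-open; always genomic ascending
        assert m.exons == [(0, 100), (200, 300)]
        assert ann["g1"].strand == strand

    def test_out_of_bounds_names_feature(self, tmp_path, flat_genome):
        p = tmp_path / "a.gff3"
        p.write_text(GFF.format(strand="+").replace("201\t300", "201\t999999"))
        with pytest.raises(ValueError, match="g1.t1"):
            core_io.read_annotation(p, flat_genome)

    def test_orphan_exons_collected(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF.format(strand="+") + "chr1\tx\texon\t500\t600\t.\t+\t.\tID=lost;Parent=ghost\n")
        ann = core_io.read_annotation(p)
        assert ann.orphan_features == ["lost"]

    def test_round_trip(self, sim, tmp_path):
        p = tmp_path / "rt.gff3"
        core_io.write_annotation(sim.annotation, p)
        back = core_io.read_annotation(p)
        assert set(back.genes) == set(sim.annotation.genes)
        for gid, g in sim.annotation.genes.items():
            g2 = back[gid]
            assert (g2.chrom, g2.strand) == (g.chrom, g.strand)
            for m, m2 in zip(g.mrnas, g2.mrnas):
                assert m2.exons == m.exons and m2.cds == m.cds


# ---------------------------------------------------------------------------
# BED12 transcripts
# ---------------------------------------------------------------------------

class TestBed12:
    def test_two_blocks(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t100\t400\tr1\t0\t+\t100\t400\t0\t2\t100,100\t0,200\n")
        ts = core_io.read_transcripts(p)
        t = ts.transcripts[0]
        assert t.exons == [(100, 200), (300, 400)]
        assert t.junction_chain() == ((200, 300),)

    def test_mono_exon(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t50\tr1\t0\t-\t0\t50\t0\t1\t50\t0\n")
        t = core_io.read_transcripts(p).transcripts[0]
        assert t.exons == [(0, 50)] and t.junction_chain() == ()

    def test_unstranded_flagged(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t50\tr1\t0\t.\t0\t50\t0\t1\t50\t0\n")
        ts = core_io.read_transcripts(p)
        assert ts.n_unstranded == 1 and ts.stranded() == []

    def test_round_trip(self, sim, tmp_path):
        p = tmp_path / "rt.bed"
        core_io.write_transcripts(sim.transcripts, p)
        back = core_io.read_transcripts(p)
        orig = {t.read_id: (t.chrom, t.strand, tuple(t.exons)) for t in sim.transcripts}
        got = {t.read_id: (t.chrom, t.strand, tuple(t.exons)) for t in back}
        assert got == orig


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t5\t.\tA\tT\t.\t.\t.
chr1\t10\t.\tA\tT,G\t.\t.\t.
"""


class TestVcf:
    def test_multiallelic_split(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF)
        vs = core_io.read_variants(p)
        assert len(vs) == 3
        assert {v.alt for v in vs if v.pos == 9} == {"T", "G"}
        assert all(v.var_class == "SNP" for v in vs)

    def test_round_trip_preserves_classes(self, sim, tmp_path):
        p = tmp_path / "rt.vcf"
        sample = sim.variants[:1000]
        core_io.write_variants(sample, p, contig_lengths=sim.genome.lengths)
        back = core_io.read_variants(p, sim.genome)
        orig = {(v.chrom, v.pos, v.alt): v.var_class for v in sample}
        got = {(v.chrom, v.pos, v.alt): v.var_class for v in back}
        assert got == orig


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

class TestIntervalUnion:
    @pytest.mark.parametrize(
        "segs,expected",
        [
            ([(0, 100), (50, 150)], 150),
            ([(0, 10), (20, 30)], 20),
            ([(0, 5)], 5),
        ],
    )
    def test_examples(self, segs, expected):
        ivs = [Interval("chr1", s, e) for s, e in segs]
        assert core_io.interval_union_length(ivs) == expected

    def test_matches_per_base_mask_oracle(self):
        rng = np.random.default_rng(42)
        starts = rng.integers(0, 9_000, size=10_000)
        lengths = rng.integers(1, 500, size=10_000)
        segs = [(int(s), int(min(s + l, 10_000))) for s, l in zip(starts, lengths)]
        mask = np.zeros(10_000, dtype=bool)
        for s, e in segs:
            mask[s:e] = True
        ivs = [Interval("chr1", s, e) for s, e in segs]
        assert core_io.interval_union_length(ivs) == int(mask.sum())


# ---------------------------------------------------------------------------
# Annotation diff
# ---------------------------------------------------------------------------

class TestDiff:
    def _base(self) -> Annotation:
        return make_annotation(
            make_gene("g1", exons=[(0, 100), (200, 300), (400, 500)]),
            make_gene("g2", exons=[(1000, 1200)]),
        )

    def test_identity(self):
        a, b = self._base(), self._base()
        assert all(v == 0 for v in core_io.diff_annotations(a, b).counts().values())

    def test_single_exon_removed(self):
        a, b = self._base(), make_annotation(
            make_gene("g1", exons=[(0, 100), (200, 300)]),
            make_gene("g2", exons=[(1000, 1200)]),
        )
        d = core_io.diff_annotations(a, b)
        assert d.counts()["exons_deleted"] == 1
        assert d.counts()["introns_deleted"] == 1  # the 300..400 gap is gone
        assert d.counts()["loci_deleted"] == 0

    def test_edit_script_counts(self):
        # b: drop gene g2 entirely (isolated locus) and add a novel isolated gene
        a = self._base()
        b = make_annotation(
            make_gene("g1", exons=[(0, 100), (200, 300), (400, 500)]),
            make_gene("g3", exons=[(5000, 5100), (5200, 5300)]),
        )
        d = core_io.diff_annotations(a, b).counts()
        assert d["loci_deleted"] == 1 and d["loci_added"] == 1
        assert d["exons_deleted"] == 1 and d["exons_added"] == 2
        assert d["introns_added"] == 1

    def test_disjoint_namespaces_raise(self):
        a = self._base()
        b = make_annotation(make_gene("gx", chrom="chrZ"))
        with pytest.raises(ValueError, match="no chromosomes"):
            core_io.diff_annotations(a, b)
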