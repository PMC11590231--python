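"""Polycistronic locus detection, linkers, frames, stop codons and motifs."""

import re

import numpy as np
import pytest

from annocensus import polycistron as pc
from annocensus.model import GenomeSequence, MrnaModel, TranscriptModel
from conftest import make_annotation, make_gene


def _tandem_annotation():
    """Two same-strand coding genes with a 300-bp intergenic linker."""
    a = make_gene("gA", strand="+", exons=[(100, 400)], cds=[(100, 400)])
    b = make_gene("gB", strand="+", exons=[(700, 1000)], cds=[(700, 1000)])
    return make_annotation(a, b)


def _flat(n=2000):
    return GenomeSequence({"chr1": "ACGT" * (n // 4)})


class TestAssignCoveredGenes:
    def test_full_coverage_of_two_genes(self):
        ann = _tandem_annotation()
        t = TranscriptModel("r1", "chr1", "+", [(100, 1000)])
        assert pc.assign_covered_genes(t, ann) == ["gA", "gB"]

    def test_partial_coverage_below_threshold(self):
        ann = _tandem_annotation()
        # covers all of gA and 10% of gB
        t = TranscriptModel("r1", "chr1", "+", [(100, 730)])
        assert pc.assign_covered_genes(t, ann, min_cds_coverage=0.5) == ["gA"]

    def test_opposite_strand_never_counts(self):
        ann = _tandem_annotation()
        t = TranscriptModel("r1", "chr1", "-", [(100, 1000)])
        assert pc.assign_covered_genes(t, ann) == []

    def test_minus_strand_transcription_order(self):
        a = make_gene("gA", strand="-", exons=[(100, 400)], cds=[(100, 400)])
        b = make_gene("gB", strand="-", exons=[(700, 1000)], cds=[(700, 1000)])
        t = TranscriptModel("r1", "chr1", "-", [(100, 1000)])
        # 5'->3' on minus strand runs right to left
        assert pc.assign_covered_genes(t, make_annotation(a, b)) == ["gB", "gA"]

    def test_matches_per_base_mask_oracle(self, sim):
        rng = np.random.default_rng(5)
        idx = pc.GeneIndex(sim.annotation)
        reads = [sim.transcripts[i] for i in rng.choice(len(sim.transcripts), 200, replace=False)]
        for t in reads:
            got = set(pc.assign_covered_genes(t, sim.annotation, index=idx))
            expect = set()
            for g in sim.annotation.coding_genes():
                if g.chrom != t.chrom or g.strand != t.strand:
                    continue
                cds = g.cds_union()
                lo, hi = cds[0][0], cds[-1][1]
                mask = np.zeros(hi - lo, dtype=bool)
                cds_mask = np.zeros(hi - lo, dtype=bool)
                for s, e in t.exons:
                    s, e = max(s, lo), min(e, hi)
                    if e > s:
                        mask[s - lo : e - lo] = True
                for s, e in cds:
                    cds_mask[s - lo : e - lo] = True
                if (mask & cds_mask).sum() / cds_mask.sum() >= 0.5:
                    expect.add(g.gene_id)
            assert got == expect


class TestDetectPolycistrons:
    def test_no_spanning_transcripts(self):
        ann = _tandem_annotation()
        reads = [TranscriptModel("r1", "chr1", "+", [(100, 400)])]
        assert pc.detect_polycistrons(reads, ann) == []

    def test_evidence_sets_merge_into_one_locus(self):
        a = make_gene("gA", strand="+", exons=[(0, 300)])
        b = make_gene("gB", strand="+", exons=[(400, 700)])
        c = make_gene("gC", strand="+", exons=[(800, 1100)])
        ann = make_annotation(a, b, c)
        reads = [
            TranscriptModel("r1", "chr1", "+", [(0, 700)]),     # covers A,B
            TranscriptModel("r2", "chr1", "+", [(400, 1100)]),  # covers B,C
        ]
        (locus,) = pc.detect_polycistrons(reads, ann)
        assert locus.member_genes == ["gA", "gB", "gC"]
        assert locus.support == 2

    def test_min_support_filters(self):
        ann = _tandem_annotation()
        reads = [TranscriptModel("r1", "chr1", "+", [(100, 1000)])]
        assert len(pc.detect_polycistrons(reads, ann, min_support=1)) == 1
        assert pc.detect_polycistrons(reads, ann, min_support=2) == []

    def test_monotone_in_thresholds(self, sim):
        reads, ann = sim.transcripts, sim.annotation
        n_default = len(pc.detect_polycistrons(reads, ann, 0.5, 1))
        assert len(pc.detect_polycistrons(reads, ann, 0.9, 1)) <= n_default
        assert len(pc.detect_polycistrons(reads, ann, 0.5, 5)) <= n_default

    def test_planted_loci_recovered_exactly(self, sim):
        loci = pc.detect_polycistrons(sim.transcripts, sim.annotation)
        got = {tuple(l.member_genes) for l in loci}
        truth = {tuple(t["members"].split(",")) for t in sim.truth.polycistrons}
        assert got == truth  # precision = recall = 1

    def test_genes_unique_across_loci(self, sim):
        loci = pc.detect_polycistrons(sim.transcripts, sim.annotation)
        members = [g for l in loci for g in l.member_genes]
        assert len(members) == len(set(members))
        for l in loci:
            assert all(sim.annotation[g].strand == l.strand for g in l.member_genes)
            assert all(sim.annotation[g].is_protein_coding for g in l.member_genes)


class TestLinkers:
    def _locus(self, read_exons):
        ann = _tandem_annotation()
        read = TranscriptModel("r1", "chr1", "+", read_exons)
        locus = pc.PolycistronicLocus("L1", "chr1", "+", ["gA", "gB"], [read])
        return ann, locus

    def test_intronless_linker_genomic_equals_spliced(self):
        g = _flat()
        ann, locus = self._locus([(100, 1000)])
        genomic = pc.linker_regions(locus, ann, g, mode="genomic")
        spliced = pc.linker_regions(locus, ann, g, mode="spliced")
        assert genomic == spliced and len(genomic[0]) == 300

    def test_intron_in_linker_shortens_spliced_form(self):
        g = _flat()
        # readthrough with a 100-bp intron inside the 300-bp linker
        ann, locus = self._locus([(100, 450), (550, 1000)])
        assert len(pc.linker_regions(locus, ann, g, mode="genomic")[0]) == 300
        assert len(pc.linker_regions(locus, ann, g, mode="spliced")[0]) == 200

    def test_overlapping_cds_gives_empty_linker(self):
        a = make_gene("gA", strand="+", exons=[(100, 500)], cds=[(100, 500)])
        b = make_gene("gB", strand="+", exons=[(400, 900)], cds=[(400, 900)])
        ann = make_annotation(a, b)
        read = TranscriptModel("r1", "chr1", "+", [(100, 900)])
        locus = pc.PolycistronicLocus("L1", "chr1", "+", ["gA", "gB"], [read])
        assert pc.linker_regions(locus, ann, _flat(), mode="spliced") == [""]

    def test_planted_linker_lengths(self, sim):
        loci = pc.detect_polycistrons(sim.transcripts, sim.annotation)
        truth = {t["members"]: t for t in sim.truth.polycistrons}
        for l in loci:
            expect = [int(x) for x in truth[",".join(l.member_genes)]["linker_lengths"].split(",")]
            seqs = pc.linker_regions(l, sim.annotation, sim.genome)
            assert [len(s) for s in seqs] == expect


class TestStopCodons:
    def test_three_genes_uniform(self):
        seq = list("A" * 3000)
        for pos, stop in ((297, "TAA"), (1297, "TAG"), (2297, "TGA")):
            seq[pos : pos + 3] = stop
        g = GenomeSequence({"chr1": "".join(seq)})
        ann = make_annotation(
            make_gene("g1", exons=[(0, 300)]),
            make_gene("g2", exons=[(1000, 1300)]),
            make_gene("g3", exons=[(2000, 2300)]),
        )
        freq = pc.stop_codon_usage(ann, g)
        assert freq == {"TAA": pytest.approx(1 / 3), "TAG": pytest.approx(1 / 3),
                        "TGA": pytest.approx(1 / 3), "other": 0.0}

    def test_minus_strand_stop(self):
        # minus-strand gene whose forward-strand leftmost codon reads TCA
        seq = "TCA" + "A" * 297
        g = GenomeSequence({"chr1": seq + "G" * 100})
        ann = make_annotation(make_gene("g1", strand="-", exons=[(0, 300)]))
        freq = pc.stop_codon_usage(ann, g)
        assert freq["TGA"] == 1.0

    def test_short_cds_excluded(self):
        g = _flat()
        ann = make_annotation(make_gene("g1", exons=[(0, 2)], cds=[(0, 2)]))
        freq = pc.stop_codon_usage(ann, g)
        assert sum(freq.values()) == 0.0

    def test_planted_stop_distribution_recovered(self, sim):
        truth = {t["gene_id"]: t["stop_codon"] for t in sim.truth.genes}
        freq = pc.stop_codon_usage(sim.annotation, sim.genome)
        n = len(truth)
        for codon in ("TAA", "TAG", "TGA"):
            expect = sum(1 for s in truth.values() if s == codon) / n
            assert freq[codon] == pytest.approx(expect)


class TestFrames:
    def _pair(self, linker: int):
        a = make_gene("gA", strand="+", exons=[(0, 300)], cds=[(0, 300)])
        b = make_gene("gB", strand="+", exons=[(300 + linker, 600 + linker)],
                      cds=[(300 + linker, 600 + linker)])
        ann = make_annotation(a, b)
        read = TranscriptModel("r1", "chr1", "+", [(0, 600 + linker)])
        locus = pc.PolycistronicLocus("L1", "chr1", "+", ["gA", "gB"], [read])
        return ann, locus

    @pytest.mark.parametrize("linker,frame", [(300, 0), (301, 1), (302, 2)])
    def test_spliced_distance_mod_three(self, linker, frame):
        ann, locus = self._pair(linker)
        (out,) = pc.relative_frames(locus, ann)
        assert out["frame"] == frame
        assert out["in_frame"] == (frame == 0)

    def test_cds_start_outside_read_is_skipped(self):
        ann, locus = self._pair(300)
        short = TranscriptModel("r2", "chr1", "+", [(0, 200)])
        (out,) = pc.relative_frames(locus, ann, transcript=short)
        assert out["skipped"]

    def test_planted_frames(self, sim):
        loci = pc.detect_polycistrons(sim.transcripts, sim.annotation)
        truth = {t["members"]: t for t in sim.truth.polycistrons}
        for l in loci:
            expect = [int(x) for x in truth[",".join(l.member_genes)]["frames"].split(",")]
            frames = [f["frame"] for f in pc.relative_frames(l, sim.annotation)]
            assert frames == expect


class TestScanMotif:
    def test_iupac_expansion(self):
        assert pc.scan_motif(["GGTACTTACAGG"], "TACTTAYA") == 1.0
        assert pc.scan_motif(["GGTACTTAGAGG"], "TACTTAYA") == 0.0

    def test_absent_motif(self):
        assert pc.scan_motif(["AAAA", "CCCC"], "TACTTAYA") == 0.0

    def test_invalid_iupac_raises(self):
        with pytest.raises(ValueError, match="IUPAC"):
            pc.scan_motif(["ACGT"], "AXGT")

    def test_matches_regex_oracle(self):
        rng = np.random.default_rng(9)
        seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(300)]
        motif = "RYN"
        frac = pc.scan_motif(seqs, motif)
        pat = re.compile("[AG][CT][ACGT]")
        expect = sum(1 for s in seqs if pat.search(s)) / len(seqs)
        assert frac == expect


class TestStats:
    def test_breakdown_conservation(self, sim):
        loci = pc.detect_polycistrons(sim.transcripts, sim.annotation)
        stats = pc.polycistron_stats(loci, sim.annotation, sim.genome)
        assert stats["pcg_total"] == pc.pcg_total_from_breakdown(stats["breakdown"])
        assert stats["n_loci"] == sum(stats["breakdown"].values())

    def test_protein_length_from_cds(self):
        # CDS of 303 nt encodes 100 aa plus the stop codon
        a = make_gene("gA", exons=[(0, 303)], cds=[(0, 303)])
        assert a.representative_mrna().cds_length / 3 - 1 == 100
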