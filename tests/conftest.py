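"""Shared fixtures: hand-built micro-annotations and one session-scoped
default synthetic run used by the recovery and acceptance tests."""

from __future__ import annotations

import pytest

from annocensus.model import Annotation, GeneModel, GenomeSequence, MrnaModel
from annocensus.synthetic_data import SimulationConfig, simulate_all


def make_gene(
    gene_id: str,
    chrom: str = "chr1",
    strand: str = "+",
    exons=((0, 100), (200, 300)),
    cds=None,
    mrna_id: str | None = None,
) -> GeneModel:
    exons = [tuple(e) for e in exons]
    cds = [tuple(c) for c in (cds if cds is not None else exons)]
    mrna = MrnaModel(mrna_id or f"{gene_id}.t1", exons=exons, cds=cds, strand=strand)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, mrnas=[mrna])


def make_annotation(*genes: GeneModel) -> Annotation:
    ann = Annotation()
    for g in genes:
        ann.add(g)
    return ann


@pytest.fixture
def flat_genome() -> GenomeSequence:
    """One 10-kb chromosome of repeating ACGT (GC 50%)."""
    return GenomeSequence({"chr1": "ACGT" * 2500})


@pytest.fixture(scope="session")
def sim():
    """The default synthetic run: 2 x 500 kb, 300 genes, planted overlap
    pairs, polycistron runs, read categories and variants."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_files(sim, tmp_path_factory):
    """The default run written to disk in all supported formats."""
    outdir = tmp_path_factory.mktemp("simrun")
    paths = sim.write_all(outdir)
    return paths
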