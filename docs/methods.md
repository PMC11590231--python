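# Methods

## Coordinate model

All interval arithmetic uses one convention — 0-based half-open — with
conversions confined to the file layer (`core_io`): GFF3 and VCF are
1-based inclusive, BED is 0-based half-open. Writers sort by
(chromosome, start, id), so identical inputs give byte-identical output
files; this is what the simulator's determinism guarantee rests on.

Genes carry one or more mRNAs; gene-level statistics (protein length, stop
codon) use a single representative mRNA per gene: the one with the longest
total CDS, ties broken by exon span and then by mRNA id. The transcribed
region of a gene is the union span of its mRNA exon chains, UTRs and
internal introns included. Genes without any CDS feature are retained but
marked non-coding and excluded from the polycistron analysis, which is
defined over protein-coding genes only.

## Splice-site census

Introns are the gaps between consecutive exons of each mRNA. The default
counting unit (`dedup_scope="gene"`) counts identical (start, end) introns
shared by isoforms of one gene once, while the same coordinates in two
different genes count twice; `"isoform"` scope counts every mRNA's introns.
The donor is the first two intron bases and the acceptor the last two, in
transcription order (reverse-complemented on the minus strand). Canonical
means exactly GT-AG. Types containing N are tallied but excluded from
donor/acceptor *type* counts, which are defined over unambiguous
dinucleotides only. Introns shorter than 4 bp, where donor and acceptor
would overlap, are excluded and logged. Report tables pool types below a
configurable share (default 0.01%) into an "Others" row, the usual
presentation for such censuses.

## Overlapping genes

Every unordered pair of genes whose transcribed spans share ≥ 1 bp is an
overlap pair. Geometry is decided from which transcriptional terminus of
each gene the shared region touches: `nested` when one span contains the
other (inner fraction = 1.0), `three_prime`/`five_prime` when both genes
overlap at that terminus (convergent/divergent antisense pairs), and
`mixed` otherwise (e.g. same-strand tandem overlaps). For the GC
comparison the two value populations are one GC% per overlapped region and
one GC% per gene transcribed span; the unit of observation matters for the
test and is fixed here explicitly. N bases are excluded from the GC
denominator; all-N intervals are dropped with a log message. The test is
Welch's (unequal-variance) two-sided *t*-test — the safer default when
nothing is known about the variances; text rendering of p-values floors at
"< 2.2e-16" while the exact value is kept numerically.

## Polycistronic loci

A transcript contributes polycistronic evidence when its exon blocks cover
the CDS union of ≥ 2 same-strand coding genes at ≥ `min_cds_coverage`
(default 0.5). The coverage threshold operationalizes "a read overlapping
two or more PCGs" and is exposed as a flag; opposite-strand coverage never
counts, since the phenomenon of interest is co-directional readthrough.
Loci are connected components of evidence transcripts with overlapping
covered-gene sets, members the union ordered 5′→3′ — so a locus counts
once even when different reads cover two vs three of its genes, and no
gene can belong to two loci. Raising `min_cds_coverage` or `min_support`
can only shrink the result (a property the tests assert).

Linkers run from the upstream gene's CDS end (stop codon inside the CDS,
boundary exclusive) to the downstream gene's CDS start. The default mode
returns the supporting transcript's exonic sequence in that span — the
sequence the RNA actually carries, which is what motif scanning should
see; genomic mode is retained for comparison. Relative reading frames are
likewise measured along the spliced supporting read, because an intron
inside a linker would otherwise scramble the frame: frame = (spliced
distance between CDS starts) mod 3, in frame iff 0. With CDS lengths
divisible by three, uniform random linker lengths put one third of pairs
in frame, which the acceptance checks verify as a null. Adjacent-gene
distance is the span gap (end→start, floored at 0); midpoint distance
would be an alternative reading, but gap matches how short linkers are
described. Motif scanning expands IUPAC codes into character classes and
reports the fraction of sequences with ≥ 1 sense-strand match.

## Isoform classification

The reference index catalogs, per gene, all isoform junction chains, the
splice-site sets they use, and the exon union. Decision order for a
stranded transcript: multi-exon reads are FSM on an exact full-chain
match, ISM on a contiguous sub-chain, otherwise they are assigned to the
same-strand gene with the largest exonic overlap (ties: lexicographic,
flagged) and called NIC when every site is in that gene's catalog or NNC
when at least one site is novel. Mono-exon reads contained in a reference
exon are FSM (mono-exon reference) or ISM; straddling exon and intron
space gives genic genomic. Reads with only intronic same-strand overlap
are genic intron; with only opposite-strand overlap, antisense; otherwise
intergenic. Junction matching is exact-coordinate: inputs are assumed to
be corrected/collapsed transcript models, so no wobble window is applied
(the parameter exists but only 0 is supported).

A unique isoform for counting purposes is a distinct (gene, junction
chain) pair; mono-exon reads use their exonic footprint. The AS summary
calls a gene alternatively spliced when it shows ≥ 2 unique isoforms.
Rarefaction samples reads without replacement (NumPy generator, seeded,
so curves are exactly reproducible) and is checked against the
hypergeometric closed form E[unique] = Σ_g (1 − C(N−c_g, n)/C(N, n)).

## Variant census

SNP: both alleles single bases. Otherwise the net length change decides:
< 50 bp indel, ≥ 50 bp SV. Balanced multi-base substitutions have no net
length change; they are binned by allele length and flagged, as are
symbolic alleles (`<DEL>`), which are SVs of unencoded size. The reference
footprint is [pos, pos + len(REF)), a 1-bp anchor for pure insertions. A
variant counts toward **every** region class (genic, coding, non-genic)
its footprint overlaps, so boundary-straddling variants are counted twice
and class counts may exceed the variant total — densities are per 100 bp
of the class's merged interval length. Per-gene density labels use
< 10/100 bp (conserved) and > 20/100 bp (variable) thresholds.

## Simulator

The simulator's job is to provide exact ground truth, not sequencing
realism. Background sequence is i.i.d. with configurable GC (default
55.7%, a typical value for the GC-rich fungal genomes this kind of census
targets). Genes are built as spliced CDS sequences (ATG, stop-free
interior, terminal stop drawn from a configured distribution, default
TGA 0.5 / TAA 0.3 / TAG 0.2) split into exons with introns inserted
between; only the constrained bases — CDS codons and intron boundary
dinucleotides — are written into the background, so UTRs and intron
interiors stay free sequence. That is what lets planted features share
genomic space without conflicts: convergent/divergent overlap pairs
overlap only in UTRs, and nested antisense genes sit inside a host
intron's unconstrained interior.

Default scale is 2 chromosomes × 500 kb with 300 genes (1–8 exons,
80–450 codons, 50–200 bp introns, 20–120 bp UTRs), 12 planted overlap
pairs, 10 polycistron runs (7×2, 2×3, 1×4 members; 100–400 bp linkers),
~12 reads per gene with 20% 5′-truncated (ISM) and 5% one-donor-shifted
(NNC) reads plus 2% antisense and 2% intergenic background reads, and
variant densities of 9 SNPs / 1.1 indels / 0.05 SVs per kb — the scale of
a dense two-haplotype comparison — placed uniformly unless a genic bias
is configured. Non-canonical splice types are planted per intron at
configured rates (defaults echo a GC-AG-dominated fungal census). The
whole run takes a few seconds on one CPU and is byte-deterministic for a
fixed seed.

What the simulator does **not** emulate: sequencing errors and quality
scores, alignment wobble around junctions, truncated reads with
non-exonic endpoints, transcript abundance structure beyond Poisson read
counts, and linkers containing introns (covered instead by hand-built
unit-test cases). Passing the recovery suite therefore shows the censuses
are exact on clean, well-aligned inputs; it does not measure robustness
to alignment noise, which exact-coordinate junction matching deliberately
does not attempt to absorb.

## Numerical and degenerate-input choices

Empty intron sets, empty GC interval lists and groups of fewer than two
values are errors, not silent zeros. Identical groups in the Welch test
return t = 0, p = 1 rather than NaN. Annotation diffing treats an exon or
intron as a unique (chrom, start, end, strand) tuple and a novel/deleted
locus as a gene with no exon overlap in the other gene set; annotations
are only rejected when their chromosome namespaces are fully disjoint,
since a legitimate correction can empty a chromosome. Unstranded
transcripts (BED strand ".") are kept and counted but excluded from all
strand-dependent analyses.
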