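# Methods

## Overview

`txguide` studies and implements gene-level read assignment for
species whose nearest reference transcriptome is substantially
diverged. The pipeline is: quality-filter reads; align each read to a
database merging one or more reference gene catalogs (and, optionally,
annotated de novo contigs); assign the read to the gene of its best
hit; assemble each gene's reads separately; validate every contig by
re-annotation against the reference; and score the result. Because the
method's accuracy can only be measured when read origins are known,
the simulator is a first-class component, not a test fixture.

## The gene catalog

A reference transcriptome maps many transcripts to one gene. Since the
goal is gene identification rather than isoform resolution, the
catalog keeps exactly one representative per gene: the longest
transcript (ties broken by the lexicographically smallest transcript
id, so ingestion order never matters). All downstream coordinates —
assignment, contig validation, completeness and contiguity — refer to
this representative of length `L_g`.

## Read simulation

`tile_reads` emits `n = ceil(coverage · L / r_eff)` reads per
transcript, `r_eff = min(read_length, L)`, with start positions spaced
evenly over `[0, L − r_eff]`; transcripts shorter than the read length
yield whole-transcript reads. Even tiling guarantees the nominal
coverage for every gene exactly and makes every dataset deterministic;
a uniform-random placement mode (`random_start`) exists for checking
that conclusions do not depend on the regular spacing. Defaults mirror
the study design this simulator serves: read-length classes 100, 150,
200 and 350 bases, 10X coverage, divergence levels 0%, 5%, 15%, 30%.

Divergence is injected as independent per-base substitution with
probability `d`, the replacement drawn uniformly from the three other
bases; no indels are simulated. This single rate deliberately folds
together sequencing error, polymorphism and species divergence. Two
consequences matter when interpreting results:

- a substituted base is never the original one, so a read's expected
  identity to the reference is exactly `1 − d`;
- two simulated reads of the same gene are mutated *independently*,
  so their expected pairwise identity in an overlap is
  `(1 − d)² + d²/3`, which is much lower than `1 − d`. Real reads from
  one individual share their species' variants and differ only by
  sequencing error, so this simulation is a worst case for
  read-to-read consensus (see "Known limitations").

Simulated reads carry constant Phred 40 so the QC stage is a no-op on
them: the simulation isolates assignment behaviour, not quality
filtering. Each gene draws from its own random sub-stream (seeded by a
CRC32 hash of the gene id combined with the global seed), so a gene's
reads are identical whether it is simulated alone or within a larger
catalog.

### Synthetic catalogs

`random_catalog` grows random gene sequences base by base under a
global screen: no 9-mer (canonical over both strands) may occur twice
anywhere in the catalog. Genes built this way are pairwise
seed-disjoint for a word size of 9 — a read can seed only on its gene
of origin — which realises the idealised no-paralog regime in which
assignment should be exact. Planted paralog pairs (mutated copies that
deliberately share k-mers) can be added to study multigene ties. The
default study conditions used by the test suite are 50 genes of 1,000
bases at 10X coverage; these sizes keep a full four-level divergence
sweep to a few minutes on one core while leaving ~5,000 reads per
condition, enough for per-gene rates to be meaningful.

## Quality control

Rules operate on the already end-trimmed read, in this order: trim 5'
and 3' bases until the first base with Phred ≥ 13; then reject when
any base < 5, when more than 10% of bases are < 13, when the mean
quality is < 20, or when fewer than 30 bases remain. Thresholds are
strict inequalities, so boundary reads (a Phred-5 base, exactly 10%
low-quality bases, mean exactly 20, length exactly 30) survive. In
paired mode a rejected mate is replaced by a 50-base all-N placeholder
to preserve record-for-record parity between R1 and R2 files; an all-N
sequence contains no ACGT 9-mer, so placeholders can never seed an
alignment, and pairs where both mates are placeholders are dropped
before assignment. Pair merging accepts the longest suffix/prefix
overlap of ≥ 8 bases at ≥ 90% identity between R1 and the
reverse-complemented R2, taking the higher-quality base and the
maximum quality at each overlapped position; this deterministic
criterion replaces the p-value test of statistical mergers so that the
package needs no external binary. The over-representation filter is an
optional cap on identical sequences, off by default — what counts as
over-representation (PCR duplication vs. genuine high expression) is
dataset-dependent, so no universal threshold is baked in.

## Alignment

The aligner is a classic seed-and-extend local aligner: an exact-match
index of all ACGT 9-mers of the subjects; query 9-mers look up
postings; hits on one subject are clustered by diagonal (gap tolerance
20); each cluster is scored by ungapped x-drop extension and then
refined by an exhaustive affine-gap Smith–Waterman restricted to a
subject window spanning the cluster's diagonals plus 50 bases of
padding — the window plays the role of the band. Scoring is the
classic nucleotide-BLAST scheme: match +2, mismatch −3, gap existence
5, gap extension 2 (a length-k gap costs 5 + 2k). The minus strand is
searched by aligning the reverse-complemented query against the
plus-strand index; subject intervals are always reported on the
subject plus strand and all coordinates are 0-based half-open.
Overlapping HSPs on the same subject and strand collapse to the
highest-scoring one. E-values are not computed and ranking uses the
raw score only; this deliberately avoids reproducing the
subject-length "attractor" artifact that e-value-based ranking can
introduce when a read ties between genes of different lengths.

`sw_oracle` is a separate, exhaustive Smith–Waterman over the full
dynamic-programming matrix (score and interval via a two-pass
end-then-start computation), sharing no code with the seeded path. It
exists purely as an independent check: tests verify that the heuristic
never exceeds the oracle's score and that, on instances with planted
homology, both name the same best-hit gene. An optional adapter runs
NCBI blastn with matching parameters for assignment-level
cross-validation; it is never part of the pipeline.

## Assignment

An HSP is accepted when it spans more than 70% of the read
(query coverage) at more than 70% identity over its alignment columns
— both strict. Among accepted HSPs the maximal raw score decides the
hit; a read's best HSP per gene represents that gene (multiple HSPs on
one gene are not summed). All genes attaining the maximal score are
recorded: more than one distinct gene sets `hit_multigene`; a single
gene reached from two or more reference sources at the best score sets
`hit_multispecies`. Under the default tie policy (`exclude`) multigene
reads count toward no individual gene and are tallied separately —
ties are a signal about paralogy, not evidence for any one member —
while `--ties=duplicate` counts a tied read once per tied gene for
sensitivity analysis. The same ambiguity applies to the evaluation
layer: by default a tied read never counts as "correctly assigned".

## Assembly and validation

The internal assembler is greedy overlap-layout-consensus: repeatedly
merge the pair of contigs with the longest suffix/prefix overlap of at
least 30 bases (matching the QC minimum read length) at ≥ 95%
identity, both orientations considered, with ties broken by
lexicographic read id so output is deterministic; merged columns keep
per-base counts and the consensus is the majority base (ties to the
alphabetically first). Every consensus base is therefore supported by
at least one member read. The assembler intentionally replaces
external assemblers so the pipeline is testable without binaries;
adapters that invoke Trinity, SPAdes (careful mode, auto coverage
cut-off) or CAP3 with their conventional options are provided and
raise an explicit error when the binary is absent rather than falling
back silently.

Validation is the same operation for internal and external contigs:
align the contig against the reference database, require the same
> 70% coverage / > 70% identity acceptance, take the best HSP's gene
(ties → multigene annotation), reverse-complement the contig when the
best strand is minus, and re-bin the contig to the gene its annotation
names — the validation annotation, not the bin it was assembled in, is
authoritative. Unannotated contigs are discarded with a logged reason.

## Coverage metrics

Completeness and contiguity are computed from the threshold-passing
HSP subject intervals of each validated contig on its gene's longest
reference transcript: `Cp` is the union coverage over all contigs,
`Ct` the coverage of the single longest contig (sequence length, ties
by smallest contig id), both clipped to `[0, L_g)` and divided by
`L_g`. Using pairwise HSP coordinates rather than a multiple alignment
of the contigs measures the same covered-base cardinality while
remaining deterministic and dependency-free. Genes with no validated
contig have undefined `Cp`/`Ct` and are excluded from those
distributions (they still count against NIG).

Gene typology uses exact comparisons (`rr == 1.0`), which is safe
because rates are ratios of small integer counts. One state the
five-way typology leaves verbally ambiguous is `rr = 0` with defined
`sr = 0` — a gene that received only foreign reads. It is classified
"mixed" (it lost all its reads *and* captured foreign ones), keeping
the categories a true partition; `rr = 0` with `sr > 0` is impossible
by construction and raises.

## Numerical and design choices

- Word size 9 and the 70%/70% acceptance thresholds are the method's
  operating point; scoring defaults are the classic blastn values, the
  least-surprising completion where only the word size is dictated.
- The x-drop parameter (20) and window padding (50) only affect which
  near-optimal alignments the heuristic considers; the oracle tests
  bound the consequences.
- FASTQ quality encoding is fixed to Phred+33; FASTA headers default
  to `geneid|transcriptid` with a configurable delimiter and field
  order, since reference header conventions vary.
- All persisted tables are TSV with deterministic row order; reruns on
  identical inputs are byte-identical, and every pipeline run writes a
  manifest (version, parameters, seed, per-stage counts).
- Degenerate inputs: empty read streams and empty gene bins are
  errors or absences, never silent successes; reads shorter than the
  word size simply produce no alignment.

## Known limitations

- Because simulated reads are mutated independently, read-to-read
  identity at divergence `d` is roughly `(1−d)² + d²/3`; at `d ≥ 0.05`
  this falls below the assembler's 95% overlap identity, so contigs
  fragment and contiguity drops sharply even while assignment (which
  compares read to *reference*) and completeness stay high. Real reads
  from one individual differ only by sequencing error, so this is a
  conservative regime for assembly; conclusions about *assignment*
  accuracy are unaffected.
- Passing tests on the synthetic catalog show correctness of the
  machinery under controlled homology, not performance on real
  transcriptomes: the generator has no expression heterogeneity, no
  indels, no isoforms, no adapter contamination, and (by default) no
  paralogs.
- The internal assembler is not a substitute for a production
  assembler's sensitivity; it exists so the orchestration, binning and
  validation logic are fully testable. External adapters reproduce the
  conventional invocations when binaries are available.
- The statistical modelling of rate-versus-length relationships
  (mixed-effect regressions) is out of scope; the evaluation TSVs are
  designed to drop straight into standard statistics packages.
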