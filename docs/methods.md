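# Methods

## Scope and model

`porebench` measures two quantities for a basecalled long-read set against
a trusted single-contig reference:

* **read accuracy** — per-read BLAST identity (matching bases divided by
  total alignment columns, insertions and deletions included), summarised
  as the median over all expected reads;
* **consensus accuracy** — the median BLAST identity of 10 kbp pieces of a
  reference-guided assembly built from the reads,

and classifies every consensus-vs-reference difference by reference
context. The central modelling assumption is the random/systematic error
dichotomy: an error carried independently by a minority of reads is
removed by majority voting at sufficient depth, while an error carried by
more than half the reads at a locus survives into the consensus regardless
of depth. Dcm-methylation motifs (CCAGG/CCTGG) and homopolymer length
errors are the two systematic channels given first-class treatment, since
they dominate the consensus error profiles of basecallers whose training
data lacked the relevant modification or length range.

## Alignment

Reads (and assembly chunks) are located by exact k-mer seeding (default
k = 15, minimum 3 collinear seeds within a drift tolerance scaled to read
length) and aligned semi-globally within the seeded window: the query is
consumed end to end, target end-gaps are free. Two engines share this
interface:

* `align_banded` — a banded affine-gap Gotoh aligner (defaults
  match +2 / mismatch −4 / gap open −4 / gap extend −2, ONT-style) with
  deterministic tie-breaking: diagonal over deletion over insertion, gap
  extension over opening. If the optimal path touches the band edge the
  caller doubles the band and retries. The test suite verifies its scores
  against an independent exhaustive dynamic program on hundreds of random
  instances.
* an `edlib` backend (default for whole read sets) — bit-parallel
  edit-distance alignment with a traceback. Unit edit costs rather than
  affine scores are immaterial for identity measurement and pileup
  construction, and the speed difference is what makes desk-scale
  simulations practical.

Circular replicons are handled by indexing and aligning against the
doubled reference and reducing coordinates modulo the reference length;
an alignment's `ref_end` may exceed the length to mark an origin-spanning
hit. One best alignment is kept per read; all coordinates are 0-based,
half-open, forward-strand (minus-strand reads are reverse-complemented
before alignment).

Identity is computed from op lengths, never op counts. Because co-optimal
alignments exist (a substitution can trade against an insertion-deletion
pair of equal edit cost), identities of the "same" read pair computed
through different alignment paths can differ in the sixth decimal; tests
that traverse the alignment layer use tolerances accordingly.

## Read-level rules

A read scores its alignment's BLAST identity if at least half of it
aligned (the rule is strictly "less than half" for the 0% penalty); reads
under that bar, unaligned reads, and reads the basecaller failed to output
at all score 0%, so selective output cannot inflate the median. The
summary reports the median identity and its qscore, N50, total bases and
the fraction of reads whose mean quality falls below a fail threshold
(default Q7). Mean read quality averages per-base *error probabilities*
and converts back to the Phred scale; averaging raw Phred values would
overweight the best bases. Read selection by reference-spanning alignment
length (the "≥ 22 kbp" style filter used to build benchmarking sets) is a
parameter, since the appropriate threshold depends on genome size and
depth.

Identity↔qscore conversion uses `q = -10·log10(1 − identity)`, capped at
Q90 by default so error-free synthetic runs keep finite summaries. The
cap is configurable and reported values at the cap simply mean "no errors
observed at this problem size".

## Consensus construction

The assembler follows the replace-then-polish recipe of reference-guided
basecaller comparison:

1. **Tiling** replaces every reachable reference span with read sequence
   (highest-identity alignments claim their spans first; uncovered spans
   keep reference sequence), so the assembly inherits the reference's
   large-scale structure but none of its small-scale basecalls.
2. **Polishing** realigns all reads to the draft and emits, at each draft
   position, the plurality symbol over {A, C, G, T, deletion}; an
   insertion is emitted after a position only when the most common
   inserted string at that junction occurs in at least half of the
   covering reads. Positions covered below `min_depth` (default 1) keep
   the draft base. Ties go to the current draft symbol, which makes
   polishing a contraction; a lexicographic tie rule is available. Up to
   `polish_rounds` (default 4) rounds run, stopping early when a round
   leaves the draft unchanged. This polisher is a deterministic stand-in
   for a partial-order-alignment polisher such as Racon — it preserves the
   majority-vote behaviour that the random/systematic analysis relies on,
   but it is not a Racon reimplementation.
3. **Iteration**: the assembly is run `iterations` (default 10) times,
   each with the reads shuffled by a seeded RNG and the reference rotated
   by ⌊i·L/iterations⌋ (circular references only; each result is rotated
   back to the canonical start by locating a 1 kbp anchor from the
   reference origin). The 10 assemblies then serve as the "reads" of one
   final assembly against the original reference.

A design point worth recording: with a deterministic, order-free plurality
polisher, shuffling the reads changes nothing unless the shuffle reaches
the draft itself. The inner iterations therefore tile in *shuffled read
order* rather than identity order. Each iteration's draft then starts from
different reads, its polish converges to a slightly different local
optimum (plurality voting cannot fix every locus — e.g. a missing base
next to two homopolymer runs whose restoring insertion votes scatter
across alignment representations and miss the 50% bar), and the final
vote across 10 diverse assemblies removes these idiosyncratic residuals.
Standalone `rebaler_lite` keeps identity-ordered tiling. Measured on 50 kbp
/ 40× / 5% random-error simulations, individual assemblies carry a
fraction of an error each on average and the meta-assembly removes
essentially all of them; the package's validation script reports this as
the relative error reduction of iteration, summarising the individual
assemblies by their *mean* error count — at desk scale these are small
integers and a median would collapse to zero resolution.

## Error taxonomy

The final assembly is aligned end-to-end to the reference and every
difference becomes an event: one substitution per mismatched column, one
event per gap run (carrying the full allele). Classification precedence is
Dcm > homopolymer > plain, with mutually exclusive classes:

* **dcm** — the event occurs in a CCAGG/CCTGG occurrence: a
  substitution's position, any deleted position, or an insertion
  junction's right neighbour lies inside a motif interval. The motif pair
  is closed under reverse complement, so a forward-strand scan covers both
  strands. All five motif positions count as "inside"; the window is
  configurable.
* **homopolymer_insertion / homopolymer_deletion** — the event changes the
  length of a reference homopolymer of three or more bases: a same-base
  insertion adjacent to (either flank of) a run of that base, or a
  deletion lying entirely within a run.
* **insertion / deletion / substitution** — everything else.

Profiles report both event counts (a multi-base indel is one error,
matching NUCmer-style reporting) and affected-base counts, which sidesteps
the one-error-or-several ambiguity for long indels; rates are per 100
reference bp and the total error percentage uses affected bases.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
nanopore physics:

* a seeded random genome at configurable length and GC (defaults 50 kbp,
  0.5), circular by default, with non-overlapping planted motif sites
  (default 100) and homopolymer runs; after planting, accidental motif
  occurrences are patched away so the motif ground truth is exhaustive,
  and planted runs are recorded at their realised maximal extent;
* reads with uniform (wrapping) starts, truncated-normal lengths (default
  5 ± 1.5 kbp, floor 500 bp), random strands, and per-read FASTQ qualities
  derived from realised identity;
* a **random channel**: i.i.d. per-base substitutions (2%), insertions
  (1%) and deletions (2%) — a 5% total split in ONT-like proportions;
* **systematic channels**, off by default: a per-read miscall of each
  planted motif's methylated cytosine (second C, configurable offset) with
  probability `dcm_error_rate`, using a per-site fixed alternative base so
  the error is coherent across reads; and a per-read ±1 length slip of
  each planted homopolymer with probability `homopolymer_slip_rate`, with
  a per-site fixed direction.

Every injected event is logged to a per-read ledger; replaying the ledger
against the reference reconstructs each read byte-for-byte (a tested
invariant), and `expected_profile` states the consensus-level profile the
majority-vote logic implies (systematic channels above 0.5 contribute
their sites; everything else contributes ≈ 0 at depth of a few tens).

What the simulator does **not** model — and hence what passing tests do
not establish about real data: signal-level artefacts, quality-score
calibration, context-dependent (non-uniform) random error, chimeras,
adapters and barcodes, the long-tailed empirical read-length
distributions of real runs, and multi-contig or diploid genomes. The
systematic channels are deliberately minimal (single-base miscall, ±1
slip): sufficient to exercise the classifier and the majority-vote logic,
not a model of basecaller behaviour.

## Problem sizes and numerical choices

Tests run on 6–20 kbp genomes at 8–20× depth; the validation script uses
50 kbp at 40× — sizes chosen so a full run stays in the minutes range on
one CPU while leaving tens of planted sites per class for recovery
statistics. All randomness flows through seeded NumPy generators; fixed
seed and inputs give bit-identical FASTA/FASTQ outputs, assemblies and
report JSON. Degenerate inputs are defined rather than fatal: zero reads
tile to the reference itself, zero alignable reads yield a 0%-accuracy
report with a warning, an assembly shorter than one chunk is a single
chunk, and a trailing chunk shorter than half the chunk size merges into
its predecessor. Chunk-identity spread is reported as the sample standard
deviation across chunks.

## Known limitations

* The polisher's insertion vote can split across co-optimal gap
  placements, so isolated missing bases adjacent to two homopolymer runs
  occasionally persist through a single assembly (this is precisely the
  residual the iterative meta-assembly removes).
* Consensus error positions inherit the leftmost-gap convention of the
  final assembly-to-reference alignment; a homopolymer length change is
  therefore reported at the run's first ambiguous junction, and in rare
  constellations an inserted base is placed just outside the run it
  lengthened and classified as a plain insertion.
* One best alignment per read: split or chimeric reads are scored by
  their single best segment, consistent with a single per-read aligned
  fraction.
* The aligner is for desk-scale benchmarking (tens of Mbp of reads
  against sub-Mbp references), not a general-purpose mapper: there is no
  minimizer sampling, chaining of multiple loci, or mapping-quality
  model.
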