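"""Chunked consensus accuracy and the consensus error taxonomy.

Consensus accuracy is measured the same way as read accuracy: the assembly
is cut into 10 kbp pieces, each piece is aligned back to the reference, and
the median BLAST identity of the pieces is the headline number (also
expressed as a qscore).

Every assembly-vs-reference difference is classified by its reference
context, with mutually exclusive classes and precedence

    Dcm  >  homopolymer insertion / homopolymer deletion  >  plain

An error is *Dcm* if it occurs inside a CCAGG/CCTGG Dcm-methylation motif
occurrence (the pair is closed under reverse complement, so a forward-strand
scan covers both strands).  An indel is a *homopolymer* error if it adds or
removes bases of a homopolymer at least three bases long in the reference.
Everything else is a plain insertion, deletion or substitution.
"""

from __future__ import annotations

import bisect
import json
import logging
import statistics
from dataclasses import dataclass, replace

from .align import (Alignment, INSERTION, MATCH, MISMATCH,
                    ReferenceIndex, blast_identity, map_read)
from .seqio import SequenceRecord, identity_to_qscore, DEFAULT_Q_CAP

__all__ = [
    "ErrorEvent",
    "ErrorProfile",
    "ConsensusSummary",
    "DCM_MOTIFS",
    "chunk_assembly",
    "consensus_identity",
    "find_motif_sites",
    "find_homopolymers",
    "MotifSites",
    "HomopolymerRuns",
    "extract_errors",
    "classify_error",
    "error_profile",
]

logger = logging.getLogger(__name__)

DCM_MOTIFS = ("CCAGG", "CCTGG")

KLASS_DCM = "dcm"
KLASS_HP_INS = "homopolymer_insertion"
KLASS_HP_DEL = "homopolymer_deletion"
KLASS_INS = "insertion"
KLASS_DEL = "deletion"
KLASS_SUB = "substitution"
ALL_KLASSES = (KLASS_DCM, KLASS_HP_INS, KLASS_HP_DEL, KLASS_INS, KLASS_DEL,
               KLASS_SUB)


@dataclass(frozen=True)
class ErrorEvent:
    """One consensus-vs-reference difference.

    ``ref_pos`` is a 0-based forward-strand reference coordinate; for an
    insertion it is the position immediately right of the junction.  The
    absent side's allele is the empty string.  ``klass`` is filled in by
    :func:`classify_error`.
    """

    ref_pos: int
    kind: str
    ref_allele: str
    alt_allele: str
    klass: str | None = None

    def __post_init__(self):
        if self.kind not in (KLASS_SUB, KLASS_INS, KLASS_DEL):
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.kind == KLASS_INS and (self.ref_allele or not self.alt_allele):
            raise ValueError("insertion must have empty ref allele")
        if self.kind == KLASS_DEL and (self.alt_allele or not self.ref_allele):
            raise ValueError("deletion must have empty alt allele")
        if self.kind == KLASS_SUB and not (len(self.ref_allele) == 1
                                           and len(self.alt_allele) == 1):
            raise ValueError("substitution alleles must be single bases")

    @property
    def length(self) -> int:
        """Number of bases the event adds, removes or changes."""
        return max(len(self.ref_allele), len(self.alt_allele))


@dataclass(frozen=True)
class ErrorProfile:
    """Per-class error tallies over a reference.

    ``counts`` tallies events (a multi-base indel is one event, matching
    NUCmer-style reporting); ``base_counts`` tallies affected bases, which
    sidesteps the one-error-or-several ambiguity for long indels.  Rates
    are events per 100 reference bp; ``total_error_pct`` is affected bases
    as a percentage of the reference length.
    """

    counts: dict[str, int]
    base_counts: dict[str, int]
    rates_per_100bp: dict[str, float]
    total_error_pct: float
    reference_length: int

    @property
    def total_events(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ConsensusSummary:
    median_chunk_identity: float
    consensus_qscore: float
    chunk_identity_sd: float
    n_chunks: int


def chunk_assembly(assembly: SequenceRecord,
                   chunk_bp: int = 10_000) -> list[SequenceRecord]:
    """Cut an assembly into consecutive ``chunk_bp`` pieces.

    A trailing piece at least half a chunk long is kept on its own;
    anything shorter is merged into the previous piece.  An assembly
    shorter than one chunk yields a single piece.
    """
    if chunk_bp < 1000:
        raise ValueError("chunk_bp must be >= 1000")
    seq = assembly.sequence
    starts = list(range(0, len(seq), chunk_bp))
    if len(starts) > 1 and len(seq) - starts[-1] < chunk_bp / 2:
        starts.pop()  # merge short tail into the previous piece
    chunks = []
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else len(seq)
        chunks.append(SequenceRecord(f"{assembly.id}_chunk{i}", seq[s:e]))
    return chunks


def consensus_identity(chunks: list[SequenceRecord],
                       reference: SequenceRecord, *,
                       circular: bool = False,
                       q_cap: float = DEFAULT_Q_CAP) -> ConsensusSummary:
    """Median BLAST identity of assembly pieces aligned to the reference."""
    if not chunks:
        raise ValueError("no chunks")
    index = ReferenceIndex(reference, circular=circular)
    identities = []
    for chunk in chunks:
        aln = map_read(chunk, index)
        if aln is None:
            logger.warning("chunk %s failed to align; identity 0", chunk.id)
            identities.append(0.0)
        else:
            identities.append(blast_identity(aln))
    median = statistics.median(identities)
    sd = statistics.stdev(identities) if len(identities) > 1 else 0.0
    return ConsensusSummary(median, identity_to_qscore(median, q_cap), sd,
                            len(identities))


class MotifSites:
    """Unioned motif occurrence intervals with O(log n) membership."""

    def __init__(self, intervals: list[tuple[int, int]]):
        merged: list[tuple[int, int]] = []
        for s, e in sorted(intervals):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.intervals = merged
        self._starts = [s for s, _ in merged]

    def __contains__(self, pos: int) -> bool:
        i = bisect.bisect_right(self._starts, pos) - 1
        return i >= 0 and pos < self.intervals[i][1]

    def overlaps(self, start: int, end: int) -> bool:
        i = bisect.bisect_right(self._starts, start) - 1
        if i >= 0 and start < self.intervals[i][1]:
            return True
        i += 1
        return i < len(self.intervals) and self.intervals[i][0] < end

    def __len__(self) -> int:
        return len(self.intervals)


def find_motif_sites(reference: SequenceRecord,
                     motifs: tuple[str, ...] = DCM_MOTIFS) -> MotifSites:
    """All forward-strand motif occurrence intervals, unioned.

    The default CCAGG/CCTGG pair is self-covering under reverse complement,
    so scanning only the forward strand still finds every site on either
    strand.
    """
    if not motifs:
        raise ValueError("no motifs given")
    seq = reference.sequence
    intervals = []
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            intervals.append((start, start + len(motif)))
            start = seq.find(motif, start + 1)  # allow overlapping hits
    return MotifSites(intervals)


@dataclass(frozen=True)
class HomopolymerRun:
    start: int
    length: int
    base: str

    @property
    def end(self) -> int:
        return self.start + self.length


class HomopolymerRuns:
    """Maximal homopolymer runs of a reference with positional lookup."""

    def __init__(self, runs: list[HomopolymerRun]):
        self.runs = sorted(runs, key=lambda r: r.start)
        self._starts = [r.start for r in self.runs]

    def __iter__(self):
        return iter(self.runs)

    def __len__(self) -> int:
        return len(self.runs)

    def run_containing(self, start: int, end: int) -> HomopolymerRun | None:
        """The run fully containing [start, end), if any."""
        i = bisect.bisect_right(self._starts, start) - 1
        if i >= 0:
            run = self.runs[i]
            if run.start <= start and end <= run.end:
                return run
        return None

    def run_adjacent(self, junction: int, base: str) -> HomopolymerRun | None:
        """A run of ``base`` touching the insertion junction (either flank).

        The junction sits between reference positions ``junction - 1`` and
        ``junction``; a run is adjacent when the junction lies inside it or
        on either of its ends.
        """
        i = bisect.bisect_right(self._starts, junction) - 1
        for j in (i, i + 1):
            if 0 <= j < len(self.runs):
                run = self.runs[j]
                if run.base == base and run.start <= junction <= run.end:
                    return run
        return None


def find_homopolymers(reference: SequenceRecord,
                      min_len: int = 3) -> HomopolymerRuns:
    """Maximal runs of identical bases with length >= ``min_len``."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = reference.sequence
    runs = []
    i = 0
    while i < len(seq):
        j = i + 1
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append(HomopolymerRun(i, j - i, seq[i]))
        i = j
    return HomopolymerRuns(runs)


def extract_errors(aln: Alignment, query: SequenceRecord,
                   reference: SequenceRecord,
                   chunk_offset: int = 0) -> list[ErrorEvent]:
    """Turn an alignment's non-match columns into error events.

    Mismatch runs are split into per-base substitutions; each gap run
    becomes a single insertion/deletion event carrying the full allele.
    ``chunk_offset`` lifts coordinates into global reference space when the
    alignment was computed against a reference excerpt.
    """
    from .seqio import reverse_complement
    oriented = query.sequence if aln.strand == "+" \
        else reverse_complement(query.sequence)
    L = len(reference.sequence)
    events: list[ErrorEvent] = []
    r, q = aln.ref_start, aln.query_start
    for op in aln.ops:
        if op.kind == MATCH:
            r += op.length
            q += op.length
        elif op.kind == MISMATCH:
            for off in range(op.length):
                pos = (chunk_offset + r + off) % L
                events.append(ErrorEvent(pos, KLASS_SUB,
                                         reference.sequence[pos],
                                         oriented[q + off]))
            r += op.length
            q += op.length
        elif op.kind == INSERTION:
            pos = (chunk_offset + r) % L
            events.append(ErrorEvent(pos, KLASS_INS, "",
                                     oriented[q:q + op.length]))
            q += op.length
        else:  # deletion
            pos = (chunk_offset + r) % L
            ref_allele = "".join(reference.sequence[(pos + k) % L]
                                 for k in range(op.length))
            events.append(ErrorEvent(pos, KLASS_DEL, ref_allele, ""))
            r += op.length
    return events


def classify_error(event: ErrorEvent, motif_sites: MotifSites,
                   homopolymers: HomopolymerRuns) -> ErrorEvent:
    """Assign an error class by reference context (Dcm > homopolymer > plain).

    Dcm membership: a substitution's position, any deleted position, or an
    insertion junction's right neighbour inside a motif interval.  A
    homopolymer insertion is a same-base insertion adjacent to a run of
    that base; a homopolymer deletion removes bases from within a run.
    """
    if event.kind == KLASS_SUB:
        in_dcm = event.ref_pos in motif_sites
    elif event.kind == KLASS_DEL:
        in_dcm = motif_sites.overlaps(event.ref_pos,
                                      event.ref_pos + len(event.ref_allele))
    else:
        in_dcm = event.ref_pos in motif_sites
    if in_dcm:
        return replace(event, klass=KLASS_DCM)
    if event.kind == KLASS_INS:
        bases = set(event.alt_allele)
        if len(bases) == 1:
            run = homopolymers.run_adjacent(event.ref_pos, event.alt_allele[0])
            if run is not None:
                return replace(event, klass=KLASS_HP_INS)
        return replace(event, klass=KLASS_INS)
    if event.kind == KLASS_DEL:
        run = homopolymers.run_containing(
            event.ref_pos, event.ref_pos + len(event.ref_allele))
        if run is not None:
            return replace(event, klass=KLASS_HP_DEL)
        return replace(event, klass=KLASS_DEL)
    return replace(event, klass=KLASS_SUB)


def error_profile(events: list[ErrorEvent],
                  reference_length: int) -> ErrorProfile:
    """Tally classified events into per-class counts and rates."""
    if reference_length < 1:
        raise ValueError("reference_length must be >= 1")
    counts = {k: 0 for k in ALL_KLASSES}
    base_counts = {k: 0 for k in ALL_KLASSES}
    for e in events:
        if e.klass is None:
            raise ValueError("events must be classified before profiling")
        counts[e.klass] += 1
        base_counts[e.klass] += e.length
    rates = {k: 100.0 * c / reference_length for k, c in counts.items()}
    total_pct = 100.0 * sum(base_counts.values()) / reference_length
    return ErrorProfile(counts, base_counts, rates, total_pct,
                        reference_length)


def write_errors_tsv(events: list[ErrorEvent], ref_id: str, path) -> None:
    """BED-like TSV export of classified error events."""
    with open(path, "w") as fh:
        fh.write("ref\tstart\tend\tkind\tklass\tref_allele\talt_allele\n")
        for e in sorted(events, key=lambda e: e.ref_pos):
            end = e.ref_pos + max(1, len(e.ref_allele))
            fh.write(f"{ref_id}\t{e.ref_pos}\t{end}\t{e.kind}\t{e.klass}\t"
                     f"{e.ref_allele or '.'}\t{e.alt_allele or '.'}\n")


def profile_to_json(profile: ErrorProfile, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "counts": profile.counts,
            "base_counts": profile.base_counts,
            "rates_per_100bp": profile.rates_per_100bp,
            "total_error_pct": profile.total_error_pct,
            "reference_length": profile.reference_length,
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")


def format_profile_table(profile: ErrorProfile) -> str:
    """Plain-text table of the error taxonomy (events, bases, rates)."""
    lines = [f"{'class':<24}{'events':>8}{'bases':>8}{'per 100 bp':>12}"]
    for k in ALL_KLASSES:
        lines.append(f"{k:<24}{profile.counts[k]:>8}"
                     f"{profile.base_counts[k]:>8}"
                     f"{profile.rates_per_100bp[k]:>12.4f}")
    lines.append(f"total error: {profile.total_error_pct:.4f}% of "
                 f"{profile.reference_length} bp")
    return "\n".join(lines)
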