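"""Reference-guided consensus assembly.

The scheme follows the Rebaler recipe used for basecaller comparison: the
reference is first *tiled* — every part of it replaced by read sequence, so
small-scale basecalls come from the reads, not the reference — and the
resulting draft is then *polished* by several rounds of realignment and
column-wise plurality voting over a pileup.  Because a single polish pass
does not always converge to the best sequence, the whole assembly is run
several times with shuffled reads and a rotated reference start, and the
per-iteration assemblies are fed as "reads" into one final assembly.  This
averages away idiosyncratic residual errors while leaving systematic errors
(shared by most reads at a locus) untouched.

The polisher is a deterministic pileup plurality vote (a stand-in for a POA
polisher such as Racon, not a reimplementation of one): at each draft
position the plurality symbol over {A, C, G, T, deletion} is emitted, and an
insertion is emitted after a position only when the most common inserted
string there occurs in at least half of the covering reads.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .align import (Alignment, DELETION, MATCH, MISMATCH, ReferenceIndex,
                    blast_identity, map_read, _edlib_infix)
from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "ConsensusParams",
    "rotate_sequence",
    "tile_reference",
    "polish_round",
    "rebaler_lite",
    "iterative_consensus",
    "IterativeResult",
]

logger = logging.getLogger(__name__)

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _BASE_TO_CODE[_b] = min(_i, 4)  # N counts toward the deletion/other bin
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes(seq: str) -> np.ndarray:
    return _BASE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class ConsensusParams:
    """Knobs of the consensus builder.

    ``polish_rounds`` is the per-assembly polishing budget (each round
    realigns all reads to the current draft; polishing stops early once a
    round leaves the draft unchanged).  ``iterations`` is the number of
    shuffled/rotated assemblies fed into the final meta-assembly.
    """

    polish_rounds: int = 4
    iterations: int = 10
    seed: int = 0
    tie_rule: str = "prefer_current"
    min_depth: int = 1
    backend: str = "edlib"
    tiling: str = "identity"

    def __post_init__(self):
        if self.iterations < 1 or self.polish_rounds < 1:
            raise ValueError("iterations and polish_rounds must be >= 1")
        if self.tie_rule not in ("prefer_current", "lexicographic"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.tiling not in ("identity", "given"):
            raise ValueError(f"unknown tiling order {self.tiling!r}")


def rotate_sequence(seq: str, offset: int) -> str:
    """Rotate a circular sequence so position ``offset`` becomes the start."""
    if not 0 <= offset < len(seq):
        raise ValueError(f"offset {offset} out of range for length {len(seq)}")
    return seq[offset:] + seq[:offset]


def _query_slice_for_ref(aln: Alignment, oriented_seq: str,
                         lo: int, hi: int) -> str:
    """Oriented-query subsequence aligned to reference interval [lo, hi).

    Coordinates are in the alignment's own (possibly >L, unwrapped)
    reference frame; interior insertions are included, boundary insertions
    fall outside the slice.
    """
    r, q = aln.ref_start, aln.query_start
    qlo = qhi = None
    for op in aln.ops:
        if op.kind in (MATCH, MISMATCH):
            if qlo is None and r + op.length > lo:
                qlo = q + max(0, lo - r)
            if r + op.length >= hi:
                qhi = q + (hi - r)
                break
            r += op.length
            q += op.length
        elif op.kind == DELETION:
            if qlo is None and r + op.length > lo:
                qlo = q
            if r + op.length >= hi:
                qhi = q
                break
            r += op.length
        else:  # insertion
            q += op.length
    if qlo is None or qhi is None:
        raise ValueError(f"interval [{lo},{hi}) outside alignment "
                         f"[{aln.ref_start},{aln.ref_end})")
    return oriented_seq[qlo:qhi]


def _uncovered_runs(covered: np.ndarray, lo: int, hi: int) -> list[tuple[int, int]]:
    """Maximal uncovered subintervals of [lo, hi) in unwrapped coordinates.

    ``covered`` is a genome-length boolean; the interval may extend past L
    (circular wrap) but runs are split at multiples of L so each maps to a
    contiguous genome slice.
    """
    L = len(covered)
    runs: list[tuple[int, int]] = []
    start = lo
    while start < hi:
        end = min(hi, ((start // L) + 1) * L)  # stay within one wrap
        seg = covered[start % L:(start % L) + (end - start)]
        holes = np.flatnonzero(~seg)
        if holes.size:
            breaks = np.flatnonzero(np.diff(holes) > 1)
            run_starts = np.concatenate(([0], breaks + 1))
            run_ends = np.concatenate((breaks, [holes.size - 1]))
            for s, e in zip(run_starts, run_ends):
                runs.append((start + int(holes[s]), start + int(holes[e]) + 1))
        start = end
    return runs


def tile_reference(reference: SequenceRecord,
                   alignments: list[Alignment],
                   reads: list[SequenceRecord],
                   order: str = "identity") -> str:
    """Replace reference spans with read sequence.

    Each alignment contributes its read's aligned subsequence over whatever
    part of its reference interval is still uncovered; spans no alignment
    reaches retain the reference sequence, so the draft always has the
    reference's large-scale structure.  With ``order="identity"`` (default)
    the highest-identity alignments claim their spans first; with
    ``order="given"`` alignments are consumed in input order, which makes
    the draft depend on a caller-supplied read shuffle — the source of
    per-iteration diversity in the shuffle/rotate meta-assembly.  With no
    reads the draft is the reference itself.
    """
    L = len(reference.sequence)
    covered = np.zeros(L, dtype=bool)
    reads_by_id = {r.id: r for r in reads}
    pieces: list[tuple[int, int, str]] = []  # (genome_start, genome_end, seq)
    if order == "identity":
        order_ = sorted(alignments,
                        key=lambda a: (-blast_identity(a), -a.ref_span,
                                       a.query_id))
    elif order == "given":
        order_ = list(alignments)
    else:
        raise ValueError(f"unknown tiling order {order!r}")
    for aln in order_:
        read = reads_by_id.get(aln.query_id)
        if read is None:
            continue
        oriented = read.sequence if aln.strand == "+" \
            else reverse_complement(read.sequence)
        for lo, hi in _uncovered_runs(covered, aln.ref_start, aln.ref_end):
            sub = _query_slice_for_ref(aln, oriented, lo, hi)
            g_lo = lo % L
            pieces.append((g_lo, g_lo + (hi - lo), sub))
            covered[g_lo:g_lo + (hi - lo)] = True
    pieces.sort()
    out: list[str] = []
    pos = 0
    for g_lo, g_hi, sub in pieces:
        out.append(reference.sequence[pos:g_lo])
        out.append(sub)
        pos = g_hi
    out.append(reference.sequence[pos:])
    return "".join(out)


def polish_round(draft: str, reads: list[SequenceRecord],
                 params: ConsensusParams, *, circular: bool = False) -> str:
    """One realign-and-vote pass over the draft.

    Builds a pileup of base/deletion counts per draft position (plus
    inserted strings keyed by the gap's left-flanking position) from fresh
    alignments of all reads to the draft, then emits the plurality symbol
    at each position.  Positions covered below ``min_depth`` keep the draft
    base; ties go to the current draft symbol under the default tie rule.
    """
    if not draft:
        raise ValueError("empty draft")
    L = len(draft)
    index = ReferenceIndex(SequenceRecord("draft", draft), circular=circular)
    counts = np.zeros((L, 5), dtype=np.int32)  # A C G T deletion
    insertions: dict[int, Counter] = defaultdict(Counter)
    for read in reads:
        aln = map_read(read, index, backend=params.backend)
        if aln is None:
            continue
        oriented = read.sequence if aln.strand == "+" \
            else reverse_complement(read.sequence)
        qcodes = _codes(oriented)
        r, q = aln.ref_start, aln.query_start
        for op in aln.ops:
            if op.kind in (MATCH, MISMATCH):
                pos = np.arange(r, r + op.length)
                if circular:
                    pos %= L
                seg = qcodes[q:q + op.length]
                valid = seg < 4  # skip N calls
                np.add.at(counts, (pos[valid], seg[valid]), 1)
                r += op.length
                q += op.length
            elif op.kind == DELETION:
                pos = np.arange(r, r + op.length)
                if circular:
                    pos %= L
                counts[pos, 4] += 1
                r += op.length
            else:
                junction = (r - 1) % L if (circular or r > 0) else -1
                insertions[junction][oriented[q:q + op.length]] += 1
                q += op.length

    cov = counts.sum(axis=1)
    draft_codes = _codes(draft)
    maxc = counts.max(axis=1)
    best = counts.argmax(axis=1)  # lowest code on ties: A<C<G<T<deletion
    draft_counts = counts[np.arange(L), np.minimum(draft_codes, 4)]
    if params.tie_rule == "prefer_current":
        keep_draft = (cov < params.min_depth) | (draft_counts == maxc)
    else:
        keep_draft = cov < params.min_depth
    choose = np.where(keep_draft, draft_codes, best)

    keep_mask = choose < 4
    base_str = _CODE_TO_BASE[choose[keep_mask]].tobytes().decode()
    emit: dict[int, str] = {}
    for junction, counter in insertions.items():
        top = max(counter.values())
        ins_seq = min(s for s, c in counter.items() if c == top)
        junction_cov = cov[junction] if junction >= 0 else int(cov[0])
        if junction_cov >= params.min_depth and 2 * top >= junction_cov:
            emit[junction] = ins_seq
    if not emit:
        return base_str
    kept_cum = np.cumsum(keep_mask)
    out: list[str] = []
    if -1 in emit:
        out.append(emit.pop(-1))
    prev = 0
    for junction in sorted(emit):
        cut = int(kept_cum[junction])
        out.append(base_str[prev:cut])
        out.append(emit[junction])
        prev = cut
    out.append(base_str[prev:])
    return "".join(out)


def rebaler_lite(reference: SequenceRecord, reads: list[SequenceRecord],
                 params: ConsensusParams, *,
                 circular: bool = False) -> SequenceRecord:
    """One reference-guided assembly: tile, then polish to convergence."""
    index = ReferenceIndex(reference, circular=circular)
    alignments = [a for a in (map_read(r, index, backend=params.backend)
                              for r in reads) if a is not None]
    draft = tile_reference(reference, alignments, reads, order=params.tiling)
    for round_no in range(params.polish_rounds):
        polished = polish_round(draft, reads, params, circular=circular)
        if polished == draft:
            logger.debug("polishing converged after %d round(s)", round_no)
            break
        draft = polished
    return SequenceRecord(f"{reference.id}_consensus", draft)


@dataclass
class IterativeResult:
    """Final meta-assembly plus the per-iteration assemblies that fed it."""

    assembly: SequenceRecord
    iteration_assemblies: list[SequenceRecord] = field(default_factory=list)


def _restore_start(assembly: SequenceRecord,
                   reference: SequenceRecord) -> SequenceRecord:
    """Rotate a circular assembly so it starts at the reference's origin,
    located by aligning a 1 kbp anchor from the reference start."""
    anchor = reference.sequence[:min(1000, len(reference.sequence))]
    doubled = assembly.sequence + assembly.sequence
    hit = _edlib_infix(anchor, doubled)
    if hit is None:
        logger.warning("could not locate origin anchor; assembly left as-is")
        return assembly
    start = hit[1] % len(assembly.sequence)
    return SequenceRecord(assembly.id,
                          rotate_sequence(assembly.sequence, start))


def iterative_consensus(reference: SequenceRecord,
                        reads: list[SequenceRecord],
                        params: ConsensusParams, *,
                        circular: bool = True) -> IterativeResult:
    """Shuffle/rotate meta-assembly.

    Runs ``params.iterations`` assemblies, each with reads shuffled by a
    seeded RNG and the reference rotated by ``i*L/iterations`` (rotation
    applies to circular references only), restores each to the canonical
    start, then assembles the iteration outputs as the read set of a final
    run against the original reference.  Same seed, same inputs: bit
    identical output.
    """
    from dataclasses import replace as _dc_replace
    rng = np.random.default_rng(params.seed)
    L = len(reference.sequence)
    # Inner iterations tile in shuffled read order: with an order-free
    # plurality polisher, the shuffle must enter through tiling for the
    # iterations to differ (each draft then carries a different read's
    # uncorrectable errors, which the final vote removes).
    inner_params = _dc_replace(params, tiling="given")
    iteration_assemblies: list[SequenceRecord] = []
    for i in range(params.iterations):
        perm = rng.permutation(len(reads))
        shuffled = [reads[int(j)] for j in perm]
        offset = (i * L) // params.iterations if circular else 0
        rotated = SequenceRecord(reference.id,
                                 rotate_sequence(reference.sequence, offset)) \
            if offset else reference
        asm = rebaler_lite(rotated, shuffled, inner_params, circular=circular)
        if circular and offset:
            asm = _restore_start(asm, reference)
        iteration_assemblies.append(SequenceRecord(f"iteration_{i}",
                                                   asm.sequence))
        logger.info("iteration %d/%d assembled (%d bp)", i + 1,
                    params.iterations, len(asm.sequence))
    final = rebaler_lite(reference, iteration_assemblies, params,
                         circular=circular)
    final = SequenceRecord(f"{reference.id}_iterative_consensus",
                           final.sequence)
    return IterativeResult(final, iteration_assemblies)
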