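"""Pairwise alignment of reads and consensus chunks to a reference.

Two engines sit behind one interface:

* :func:`align_banded` — a from-scratch banded affine-gap dynamic-programming
  aligner (semi-global: the query is consumed in full, target end-gaps are
  free).  Deterministic tie-breaking makes alignments, and hence downstream
  error events, reproducible.  This is the reference implementation and is
  cross-checked against an exhaustive DP oracle in the test suite.
* an `edlib` backend — bit-parallel edit-distance alignment used as the fast
  mapping path for whole read sets.  edlib optimises unit edit cost rather
  than the affine scheme, which is immaterial for identity measurement and
  pileup construction.

Mapping a read is seed-then-extend: exact k-mer seeds vote for a reference
window and strand (collinear within a diagonal band), then the window is
aligned.  Circular references are handled by aligning against the doubled
sequence and reducing coordinates modulo the reference length, so reads that
span the origin map contiguously.

All coordinates are 0-based, half-open, on the forward reference strand.
Reads seeded on the minus strand are reverse-complemented before alignment;
``query_start``/``query_end`` refer to the oriented (strand-applied) query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "AlignOp",
    "Alignment",
    "ScoringScheme",
    "BandTooNarrow",
    "SeedAnchor",
    "ReferenceIndex",
    "align_banded",
    "align_banded_auto",
    "blast_identity",
    "aligned_fraction",
    "seed_anchor",
    "map_read",
    "align_global",
]

MATCH = "match"
MISMATCH = "mismatch"
INSERTION = "insertion"  # extra query bases (gap in reference)
DELETION = "deletion"    # missing reference bases (gap in query)

_NEG = float("-inf")


@dataclass(frozen=True)
class AlignOp:
    kind: str
    length: int

    def __post_init__(self):
        if self.kind not in (MATCH, MISMATCH, INSERTION, DELETION):
            raise ValueError(f"unknown op kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("op length must be >= 1")


def merge_ops(ops: list[AlignOp]) -> list[AlignOp]:
    """Coalesce adjacent ops of identical kind."""
    merged: list[AlignOp] = []
    for op in ops:
        if merged and merged[-1].kind == op.kind:
            merged[-1] = AlignOp(op.kind, merged[-1].length + op.length)
        else:
            merged.append(op)
    return merged


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring: reward for a match, penalties for the rest.

    Defaults are ONT-style (minimap2-like map-ont values).
    """

    match: int = 2
    mismatch: int = 4
    gap_open: int = 4
    gap_extend: int = 2

    def __post_init__(self):
        if self.match <= 0 or min(self.mismatch, self.gap_open, self.gap_extend) <= 0:
            raise ValueError("match reward and penalties must be positive")

    def score_ops(self, ops: list[AlignOp]) -> int:
        score = 0
        for op in ops:
            if op.kind == MATCH:
                score += self.match * op.length
            elif op.kind == MISMATCH:
                score -= self.mismatch * op.length
            else:
                score -= self.gap_open + self.gap_extend * op.length
        return score


@dataclass
class Alignment:
    """A pairwise alignment as a run-length op list plus its coordinates."""

    query_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str
    ops: list[AlignOp]
    score: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.ops:
            raise ValueError("alignment has no ops")
        self.ops = merge_ops(self.ops)
        if self.ops[0].kind in (INSERTION, DELETION) or \
           self.ops[-1].kind in (INSERTION, DELETION):
            raise ValueError("alignment must begin and end with match/mismatch")
        ref_span = sum(o.length for o in self.ops if o.kind != INSERTION)
        query_span = sum(o.length for o in self.ops if o.kind != DELETION)
        if ref_span != self.ref_end - self.ref_start:
            raise ValueError("op lengths inconsistent with reference interval")
        if query_span != self.query_end - self.query_start:
            raise ValueError("op lengths inconsistent with query interval")

    # -- convenience tallies (lengths, not op counts) --
    @property
    def n_matches(self) -> int:
        return sum(o.length for o in self.ops if o.kind == MATCH)

    @property
    def n_mismatches(self) -> int:
        return sum(o.length for o in self.ops if o.kind == MISMATCH)

    @property
    def n_insertions(self) -> int:
        return sum(o.length for o in self.ops if o.kind == INSERTION)

    @property
    def n_deletions(self) -> int:
        return sum(o.length for o in self.ops if o.kind == DELETION)

    @property
    def n_columns(self) -> int:
        return sum(o.length for o in self.ops)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    def cigar(self) -> str:
        codes = {MATCH: "=", MISMATCH: "X", INSERTION: "I", DELETION: "D"}
        return "".join(f"{o.length}{codes[o.kind]}" for o in self.ops)


def blast_identity(aln: Alignment) -> float:
    """Matching bases divided by total alignment columns (incl. indels)."""
    cols = aln.n_columns
    if cols == 0:
        raise ValueError("empty alignment")
    return aln.n_matches / cols


def aligned_fraction(aln: Alignment | None, read_length: int) -> float:
    """Fraction of the read covered by its alignment; 0 for unaligned."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if aln is None:
        return 0.0
    return (aln.query_end - aln.query_start) / read_length


class BandTooNarrow(Exception):
    """The optimal banded path touched the band edge; widen and retry."""


def align_banded(query: str, target: str, scoring: ScoringScheme | None = None,
                 band: int = 32, *, query_id: str = "query",
                 ref_id: str = "target") -> Alignment:
    """Semi-global affine-gap alignment restricted to a diagonal band.

    The query is aligned end to end; gaps at either end of the target are
    free.  The band admits diagonals ``j - i`` in
    ``[min(0, n-m) - band, max(0, n-m) + band]``, which always connects the
    corners.  Raises :class:`BandTooNarrow` if the optimal path within the
    band touches its edge (the true optimum may then lie outside).

    Tie-breaking is deterministic: diagonal (match/mismatch) is preferred
    over deletion over insertion, and gap extension over gap opening.
    """
    if scoring is None:
        scoring = ScoringScheme()
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    if band < 1:
        raise ValueError("band must be >= 1")
    m, n = len(query), len(target)
    dlo = min(0, n - m) - band
    dhi = max(0, n - m) + band
    width = dhi - dlo + 1
    go, ge = scoring.gap_open, scoring.gap_extend

    # Row-banded matrices: index w maps to j = i + dlo + w.
    # M: ends diagonally; Ix: ends in insertion (consumes query);
    # Iy: ends in deletion (consumes target).
    M_prev = [_NEG] * width
    Ix_prev = [_NEG] * width
    Iy_prev = [_NEG] * width
    H_prev = [_NEG] * width
    for w in range(width):
        j = 0 + dlo + w
        if 0 <= j <= n:
            H_prev[w] = 0.0  # free target prefix
    rows_M = [M_prev]
    rows_Ix = [Ix_prev]
    rows_Iy = [Iy_prev]
    rows_H = [H_prev]

    for i in range(1, m + 1):
        M_cur = [_NEG] * width
        Ix_cur = [_NEG] * width
        Iy_cur = [_NEG] * width
        H_cur = [_NEG] * width
        qc = query[i - 1]
        for w in range(width):
            j = i + dlo + w
            if j < 0 or j > n:
                continue
            if j > 0:
                h_diag = H_prev[w]  # (i-1, j-1) is same index in prev row
                if h_diag > _NEG:
                    s = scoring.match if qc == target[j - 1] else -scoring.mismatch
                    M_cur[w] = h_diag + s
            # insertion: from (i-1, j) -> index w+1 in prev row
            if w + 1 < width:
                open_sc = rows_H[-1][w + 1]
                ext_sc = Ix_prev[w + 1]
                best = max(open_sc - go - ge if open_sc > _NEG else _NEG,
                           ext_sc - ge if ext_sc > _NEG else _NEG)
                Ix_cur[w] = best
            # deletion: from (i, j-1) -> index w-1 in current row
            if w - 1 >= 0 and j > 0:
                open_sc = H_cur[w - 1]
                ext_sc = Iy_cur[w - 1]
                best = max(open_sc - go - ge if open_sc > _NEG else _NEG,
                           ext_sc - ge if ext_sc > _NEG else _NEG)
                Iy_cur[w] = best
            H_cur[w] = max(M_cur[w], Iy_cur[w], Ix_cur[w])
        M_prev, Ix_prev, Iy_prev, H_prev = M_cur, Ix_cur, Iy_cur, H_cur
        rows_M.append(M_cur)
        rows_Ix.append(Ix_cur)
        rows_Iy.append(Iy_cur)
        rows_H.append(H_cur)

    # Free target suffix: best H in the last row; smallest j on ties.
    best_w, best_score = -1, _NEG
    for w in range(width):
        j = m + dlo + w
        if 0 <= j <= n and rows_H[m][w] > best_score:
            best_score, best_w = rows_H[m][w], w
    if best_w < 0 or best_score == _NEG:
        raise BandTooNarrow(f"band {band} cannot connect corners")

    # Traceback with tie preference M > Iy (deletion) > Ix (insertion).
    ops_rev: list[AlignOp] = []
    i, w = m, best_w
    j = i + dlo + w
    end_j = j
    full_band = width >= n + m + 1
    state = _argstate(rows_M[i][w], rows_Iy[i][w], rows_Ix[i][w])
    while i > 0:
        if not full_band and (w == 0 or w == width - 1) and 0 < j < n:
            raise BandTooNarrow(f"optimal path touched band edge at ({i},{j})")
        if state == "M":
            kind = MATCH if query[i - 1] == target[j - 1] else MISMATCH
            ops_rev.append(AlignOp(kind, 1))
            i -= 1
            j -= 1
            if i == 0:
                break
            state = _argstate(rows_M[i][w], rows_Iy[i][w], rows_Ix[i][w])
        elif state == "Iy":  # deletion consumes target
            ops_rev.append(AlignOp(DELETION, 1))
            val = rows_Iy[i][w]
            j -= 1
            w -= 1
            # prefer extending the gap on ties
            if rows_Iy[i][w] > _NEG and abs(rows_Iy[i][w] - ge - val) < 1e-9:
                state = "Iy"
            else:
                state = _argstate(rows_M[i][w], rows_Iy[i][w], rows_Ix[i][w])
        else:  # Ix: insertion consumes query
            ops_rev.append(AlignOp(INSERTION, 1))
            val = rows_Ix[i][w]
            i -= 1
            w += 1
            if i == 0:
                break
            if rows_Ix[i][w] > _NEG and abs(rows_Ix[i][w] - ge - val) < 1e-9:
                state = "Ix"
            else:
                state = _argstate(rows_M[i][w], rows_Iy[i][w], rows_Ix[i][w])

    start_j = j
    ops = merge_ops(ops_rev[::-1])
    q_start, q_end = 0, m
    # enforce the match/mismatch-terminal invariant
    while ops and ops[0].kind in (INSERTION, DELETION):
        op = ops.pop(0)
        if op.kind == INSERTION:
            q_start += op.length
        else:
            start_j += op.length
    while ops and ops[-1].kind in (INSERTION, DELETION):
        op = ops.pop()
        if op.kind == INSERTION:
            q_end -= op.length
        else:
            end_j -= op.length
    if not ops:
        raise ValueError("degenerate alignment (no aligned columns)")
    # score is the DP optimum; terminal insertions trimmed from the op list
    # (to keep match/mismatch-terminal ops) still paid their penalty
    return Alignment(query_id, ref_id, start_j, end_j, q_start, q_end, "+",
                     ops, score=int(best_score))


def _argstate(m_val: float, iy_val: float, ix_val: float) -> str:
    best = max(m_val, iy_val, ix_val)
    if m_val == best:
        return "M"
    if iy_val == best:
        return "Iy"
    return "Ix"


def align_banded_auto(query: str, target: str,
                      scoring: ScoringScheme | None = None,
                      band: int = 32, max_band: int | None = None,
                      **kw) -> Alignment:
    """Run :func:`align_banded`, doubling the band until the path fits."""
    if max_band is None:
        max_band = max(len(query), len(target))
    while True:
        try:
            return align_banded(query, target, scoring, band, **kw)
        except BandTooNarrow:
            if band >= max_band:
                raise
            band = min(band * 2, max_band)


# ---------------------------------------------------------------------------
# edlib interop

_CIGAR_RE = re.compile(r"(\d+)([=XID])")
_CIGAR_KIND = {"=": MATCH, "X": MISMATCH, "I": INSERTION, "D": DELETION}


def _ops_from_cigar(cigar: str) -> list[AlignOp]:
    ops = [AlignOp(_CIGAR_KIND[code], int(num))
           for num, code in _CIGAR_RE.findall(cigar)]
    return merge_ops(ops)


def _trim_terminal_indels(ops, ref_start, ref_end, q_start, q_end):
    ops = list(ops)
    while ops and ops[0].kind in (INSERTION, DELETION):
        op = ops.pop(0)
        if op.kind == INSERTION:
            q_start += op.length
        else:
            ref_start += op.length
    while ops and ops[-1].kind in (INSERTION, DELETION):
        op = ops.pop()
        if op.kind == INSERTION:
            q_end -= op.length
        else:
            ref_end -= op.length
    return ops, ref_start, ref_end, q_start, q_end


def _edlib_infix(query: str, target: str):
    """Infix (HW) edlib alignment; returns (ops, t_start, t_end, q_start, q_end)."""
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t_start, t_end_incl = res["locations"][0]
    if t_start is None:
        t_start = 0
    ops = _ops_from_cigar(res["cigar"])
    ops, ts, te, qs, qe = _trim_terminal_indels(
        ops, t_start, t_end_incl + 1, 0, len(query))
    if not ops:
        return None
    return ops, ts, te, qs, qe


# ---------------------------------------------------------------------------
# Seeding and read mapping

@dataclass(frozen=True)
class SeedAnchor:
    """Candidate mapping region: a window on the (possibly doubled)
    reference plus the strand that produced collinear seed hits."""

    window_start: int
    window_end: int
    strand: str
    seed_count: int


class ReferenceIndex:
    """Exact k-mer index of a reference, built once per run.

    For circular references the sequence is doubled so origin-spanning
    reads seed and align contiguously; mapped coordinates are reduced
    modulo the reference length (``ref_end`` may exceed it for wrapping
    alignments).
    """

    def __init__(self, reference: SequenceRecord, k: int = 15,
                 circular: bool = False, max_occ: int = 100):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.reference = reference
        self.k = k
        self.circular = circular
        self.length = len(reference.sequence)
        self.seq = reference.sequence + reference.sequence if circular \
            else reference.sequence
        index: dict[str, list[int]] = {}
        for i in range(len(self.seq) - k + 1):
            index.setdefault(self.seq[i:i + k], []).append(i)
        self.index = {km: pos for km, pos in index.items()
                      if len(pos) <= max_occ}


def seed_anchor(read: SequenceRecord, index: ReferenceIndex, *,
                min_seed_count: int = 3, margin_frac: float = 0.15,
                max_seeds: int = 200) -> SeedAnchor | None:
    """Locate the reference window/strand with the most collinear k-mer hits.

    Hits are collinear when their diagonals (ref pos − read pos) agree to
    within a drift tolerance scaled to the read length (indels make exact
    diagonals drift).  Returns ``None`` for reads shorter than k or with
    fewer than ``min_seed_count`` collinear seeds on either strand.
    """
    k = index.k
    n = len(read.sequence)
    if n < k:
        return None
    stride = max(1, (n - k + 1) // max_seeds)
    tol = max(50, n // 10)
    margin = int(margin_frac * n) + 20
    best: SeedAnchor | None = None
    for strand in "+-":
        seq = read.sequence if strand == "+" else reverse_complement(read.sequence)
        diags: list[int] = []
        for qpos in range(0, n - k + 1, stride):
            for p in index.index.get(seq[qpos:qpos + k], ()):
                diags.append(p - qpos)
        if len(diags) < min_seed_count:
            continue
        diags.sort()
        # densest window of diagonals within the drift tolerance
        lo = 0
        best_cnt, best_lo, best_hi = 0, 0, 0
        for hi in range(len(diags)):
            while diags[hi] - diags[lo] > tol:
                lo += 1
            if hi - lo + 1 > best_cnt:
                best_cnt, best_lo, best_hi = hi - lo + 1, lo, hi
        if best_cnt < min_seed_count:
            continue
        dmin, dmax = diags[best_lo], diags[best_hi]
        ws = max(0, dmin - margin)
        we = min(len(index.seq), dmax + n + margin)
        cand = SeedAnchor(ws, we, strand, best_cnt)
        if best is None or cand.seed_count > best.seed_count:
            best = cand
    return best


def map_read(read: SequenceRecord, index: ReferenceIndex, *,
             scoring: ScoringScheme | None = None, backend: str = "edlib",
             min_seed_count: int = 3, band: int = 64) -> Alignment | None:
    """Seed-and-extend a read against the indexed reference.

    Returns a single best alignment with forward-strand reference
    coordinates (``ref_start`` in ``[0, L)``; ``ref_end`` may exceed L for
    origin-spanning alignments on circular references), or ``None`` if the
    read cannot be anchored.
    """
    if scoring is None:
        scoring = ScoringScheme()
    anchor = seed_anchor(read, index, min_seed_count=min_seed_count)
    if anchor is None:
        return None
    oriented = read.sequence if anchor.strand == "+" \
        else reverse_complement(read.sequence)
    target = index.seq[anchor.window_start:anchor.window_end]
    if backend == "edlib":
        hit = _edlib_infix(oriented, target)
        if hit is None:
            return None
        ops, ts, te, qs, qe = hit
    elif backend == "banded":
        try:
            aln = align_banded_auto(oriented, target, scoring, band)
        except (BandTooNarrow, ValueError):
            return None
        ops, ts, te = aln.ops, aln.ref_start, aln.ref_end
        qs, qe = aln.query_start, aln.query_end
    else:
        raise ValueError(f"unknown backend {backend!r}")
    ref_start = anchor.window_start + ts
    ref_end = anchor.window_start + te
    if index.circular and ref_start >= index.length:
        ref_start -= index.length
        ref_end -= index.length
    return Alignment(read.id, index.reference.id, ref_start, ref_end,
                     qs, qe, anchor.strand, ops,
                     score=scoring.score_ops(ops))


def align_global(query: SequenceRecord, reference: SequenceRecord, *,
                 scoring: ScoringScheme | None = None) -> Alignment:
    """End-to-end (NW) alignment of two similar-length sequences.

    Used for assembly-vs-reference error extraction where both sequences
    cover the whole molecule and share a canonical start.
    """
    if scoring is None:
        scoring = ScoringScheme()
    res = edlib.align(query.sequence, reference.sequence, mode="NW", task="path")
    ops = _ops_from_cigar(res["cigar"])
    ops, rs, re_, qs, qe = _trim_terminal_indels(
        ops, 0, len(reference.sequence), 0, len(query.sequence))
    return Alignment(query.id, reference.id, rs, re_, qs, qe, "+", ops,
                     score=scoring.score_ops(ops))


def write_alignments_tsv(alignments: list[Alignment], path) -> None:
    """PAF-like TSV export of alignments for inspection."""
    with open(path, "w") as fh:
        fh.write("query\tref\tstrand\tref_start\tref_end\tquery_start\t"
                 "query_end\tidentity\tcigar\n")
        for a in alignments:
            fh.write(f"{a.query_id}\t{a.ref_id}\t{a.strand}\t{a.ref_start}\t"
                     f"{a.ref_end}\t{a.query_start}\t{a.query_end}\t"
                     f"{blast_identity(a):.6f}\t{a.cigar()}\n")
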