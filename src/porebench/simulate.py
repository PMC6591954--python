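"""Synthetic references and long reads with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale: a haploid bacterial-like reference (configurable
length and GC) carrying planted CCAGG/CCTGG Dcm motifs and homopolymer
runs, and long reads corrupted by two kinds of channel:

* a *random* channel — i.i.d. per-base substitutions, insertions and
  deletions, which majority-vote consensus should remove; and
* *systematic* channels — a per-read miscall of the Dcm motif's methylated
  cytosine, and a per-read ±1 homopolymer length slip, each applied at a
  planted site with a configured probability.  When that probability
  exceeds one half, the error wins the consensus vote and must surface in
  the final error profile with the matching class.

Every injected difference is logged to a per-read ledger, so tests can
replay the ledger to reconstruct each read exactly and can compare the
pipeline's recovered error profile against :func:`expected_profile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (ErrorProfile, ALL_KLASSES, KLASS_DCM, KLASS_HP_DEL,
                     KLASS_HP_INS)
from .seqio import SequenceRecord, identity_to_qscore, reverse_complement

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "PlantedMotif",
    "PlantedRun",
    "InjectedEvent",
    "ReadLedger",
    "generate_reference",
    "simulate_reads",
    "expected_profile",
    "replay_read",
    "write_truth_tsv",
]

_BASES = "ACGT"

SUB = "substitution"
INS = "insertion"
DEL = "deletion"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated benchmarking run.

    Defaults describe a desk-scale bacterial surrogate: a 50 kbp circular
    genome at balanced GC with 100 planted Dcm motif sites, sequenced to
    40x mean depth by 5 kbp reads carrying 5% random error split in
    ONT-like proportions (2% substitution, 1% insertion, 2% deletion).
    The systematic channels default to off; recovery experiments switch
    them on explicitly.
    """

    genome_bp: int = 50_000
    gc: float = 0.5
    n_motif_sites: int = 100
    homopolymer_spec: tuple[tuple[str, int, int], ...] = (
        ("A", 6, 10), ("C", 5, 10), ("G", 5, 10), ("T", 6, 10))
    depth: float = 40.0
    read_len_mean: int = 5_000
    read_len_sd: int = 1_500
    min_read_len: int = 500
    sub_rate: float = 0.02
    ins_rate: float = 0.01
    del_rate: float = 0.02
    dcm_error_rate: float = 0.0
    homopolymer_slip_rate: float = 0.0
    circular: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("gc", "sub_rate", "ins_rate", "del_rate",
                     "dcm_error_rate", "homopolymer_slip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.genome_bp < 1000:
            raise ValueError("genome_bp must be >= 1000")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_len_mean < self.min_read_len:
            raise ValueError("read_len_mean below min_read_len")
        occupied = 7 * self.n_motif_sites + sum(
            (length + 2) * count for _, length, count in self.homopolymer_spec)
        if occupied > self.genome_bp // 2:
            raise ValueError(
                f"planted features need {occupied} bp, more than half of "
                f"the {self.genome_bp} bp genome")


@dataclass(frozen=True)
class PlantedMotif:
    start: int
    motif: str
    miscall_offset: int  # offset of the methylated C within the motif
    alt_base: str        # the systematic miscall, fixed per site


@dataclass(frozen=True)
class PlantedRun:
    start: int
    length: int
    base: str
    slip_direction: int  # +1 insertion slip, -1 deletion slip; fixed per site

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class InjectedEvent:
    ref_pos: int   # for insertions: position immediately right of the junction
    kind: str
    ref_allele: str
    alt_allele: str
    channel: str   # random | dcm | homopolymer


@dataclass
class ReadLedger:
    read_id: str
    start: int        # reference start (forward strand)
    ref_span: int     # reference bases covered
    strand: str
    events: list[InjectedEvent] = field(default_factory=list)


@dataclass
class SimulationTruth:
    """Reference plus the planted features and per-read event ledgers."""

    reference: SequenceRecord
    motifs: list[PlantedMotif] = field(default_factory=list)
    runs: list[PlantedRun] = field(default_factory=list)
    ledgers: dict[str, ReadLedger] = field(default_factory=dict)


def _random_genome(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def generate_reference(config: SimulationConfig) -> SimulationTruth:
    """Seeded random genome with recorded, non-overlapping planted features.

    After planting, the genome is rescanned and any accidental CCAGG/CCTGG
    occurrence outside the recorded sites is patched away, so the motif
    truth is exact.  Homopolymer run coordinates are recorded as the maximal
    run actually present around each planted site.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_bp
    genome = _random_genome(rng, L, config.gc)
    occupied = np.zeros(L, dtype=bool)

    def claim(start: int, length: int) -> bool:
        lo, hi = max(0, start - 1), min(L, start + length + 1)
        if occupied[lo:hi].any():
            return False
        occupied[lo:hi] = True
        return True

    def place(length: int, max_tries: int = 2000) -> int:
        for _ in range(max_tries):
            pos = int(rng.integers(1, L - length - 1))
            if claim(pos, length):
                return pos
        raise RuntimeError("could not place feature; genome too crowded")

    motifs: list[PlantedMotif] = []
    from .errors import DCM_MOTIFS
    for _ in range(config.n_motif_sites):
        pos = place(5)
        motif = DCM_MOTIFS[int(rng.integers(0, 2))]
        genome[pos:pos + 5] = [_BASES.index(b) for b in motif]
        alt = "AGT"[int(rng.integers(0, 3))]  # anything but the true C
        motifs.append(PlantedMotif(pos, motif, 1, alt))

    planted_run_starts: list[tuple[int, int, str]] = []
    for base, length, count in config.homopolymer_spec:
        for _ in range(count):
            pos = place(length)
            genome[pos:pos + length] = _BASES.index(base)
            direction = 1 if rng.random() < 0.5 else -1
            planted_run_starts.append((pos, direction, base))

    # patch accidental motif occurrences so the recorded sites are exhaustive
    recorded = {m.start for m in motifs}
    seq = "".join(_BASES[c] for c in genome)
    for _ in range(200):
        dirty = False
        for motif in DCM_MOTIFS:
            start = seq.find(motif)
            while start != -1:
                if start not in recorded:
                    free = [p for p in range(start, start + 5)
                            if not occupied[p]]
                    if not free:
                        raise RuntimeError(
                            f"cannot patch motif at {start}: overlaps features")
                    p = free[len(free) // 2]
                    old = genome[p]
                    genome[p] = (old + 1 + int(rng.integers(0, 3))) % 4
                    seq = "".join(_BASES[c] for c in genome)
                    dirty = True
                start = seq.find(motif, start + 1)
        if not dirty:
            break
    else:
        raise RuntimeError("motif patching did not converge")

    # record planted runs at their realised maximal extent
    runs: list[PlantedRun] = []
    for pos, direction, base in planted_run_starts:
        s = pos
        while s > 0 and seq[s - 1] == base:
            s -= 1
        e = pos
        while e < L and seq[e] == base:
            e += 1
        runs.append(PlantedRun(s, e - s, base, direction))

    reference = SequenceRecord("sim_reference", seq)
    return SimulationTruth(reference, motifs, runs)


def _build_read(refseq: str, L: int, start: int, span: int,
                events: list[InjectedEvent], strand: str) -> str:
    """Apply a ledger's events while walking the covered reference span."""
    subs = {e.ref_pos: e.alt_allele for e in events if e.kind == SUB}
    dels = set()
    for e in events:
        if e.kind == DEL:
            for k in range(len(e.ref_allele)):
                dels.add((e.ref_pos + k) % L)
    inserts = {}
    for e in events:
        if e.kind == INS:
            inserts[e.ref_pos] = inserts.get(e.ref_pos, "") + e.alt_allele
    out: list[str] = []
    for u in range(start, start + span):
        g = u % L
        if g in inserts:
            out.append(inserts[g])
        if g in dels:
            continue
        out.append(subs.get(g, refseq[g]))
    seq = "".join(out)
    return reverse_complement(seq) if strand == "-" else seq


def simulate_reads(truth: SimulationTruth, config: SimulationConfig
                   ) -> tuple[list[SequenceRecord], dict[str, ReadLedger]]:
    """Draw reads to the configured depth, injecting and logging all errors.

    Read starts are uniform (wrapping on circular genomes), lengths come
    from a truncated normal, and strands are random.  Systematic channels
    are applied first (per planted site, per read), then the random channel
    fills in i.i.d. errors at untouched positions.  FASTQ qualities are
    uniform per read, derived from its realised identity.
    """
    rng = np.random.default_rng(config.seed + 1)
    refseq = truth.reference.sequence
    L = len(refseq)
    target_bases = config.depth * L
    reads: list[SequenceRecord] = []
    ledgers: dict[str, ReadLedger] = {}
    total = 0
    idx = 0
    max_span = L if config.circular else L
    while total < target_bases:
        span = int(round(rng.normal(config.read_len_mean, config.read_len_sd)))
        span = max(config.min_read_len, min(span, max_span))
        if config.circular:
            start = int(rng.integers(0, L))
        else:
            start = int(rng.integers(0, max(1, L - span + 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        events: list[InjectedEvent] = []
        taken = set()  # reference positions already owned by an event

        for m in truth.motifs:
            pos = m.start + m.miscall_offset
            if _inside(start, span, pos, L) and rng.random() < config.dcm_error_rate:
                events.append(InjectedEvent(pos, SUB, refseq[pos], m.alt_base,
                                            "dcm"))
                taken.add(pos)
        for run in truth.runs:
            if not (_inside(start, span, run.start, L)
                    and _inside(start, span, (run.end - 1) % L, L)
                    and _inside(start, span, run.end % L, L)):
                continue
            if rng.random() < config.homopolymer_slip_rate:
                if run.slip_direction > 0:
                    pos = run.end % L
                    events.append(InjectedEvent(pos, INS, "", run.base,
                                                "homopolymer"))
                else:
                    pos = (run.end - 1) % L
                    events.append(InjectedEvent(pos, DEL, run.base, "",
                                                "homopolymer"))
                    taken.add(pos)

        # random channel, vectorised over the covered span
        offsets = np.arange(span)
        r_sub = rng.random(span)
        r_del = rng.random(span)
        r_ins = rng.random(span)
        alt_shift = rng.integers(1, 4, size=span)
        ins_base = rng.integers(0, 4, size=span)
        for off in np.flatnonzero(r_sub < config.sub_rate):
            g = (start + int(off)) % L
            if g in taken:
                continue
            alt = _BASES[(_BASES.index(refseq[g]) + int(alt_shift[off])) % 4]
            events.append(InjectedEvent(g, SUB, refseq[g], alt, "random"))
            taken.add(g)
        for off in np.flatnonzero(r_del < config.del_rate):
            g = (start + int(off)) % L
            if g in taken:
                continue
            events.append(InjectedEvent(g, DEL, refseq[g], "", "random"))
            taken.add(g)
        ins_positions = {e.ref_pos for e in events if e.kind == INS}
        for off in np.flatnonzero(r_ins < config.ins_rate):
            g = (start + int(off)) % L
            if g in ins_positions:
                continue
            events.append(InjectedEvent(g, INS, "", _BASES[int(ins_base[off])],
                                        "random"))
            ins_positions.add(g)

        read_id = f"read_{idx:05d}"
        seq = _build_read(refseq, L, start, span, events, strand)
        n_err_cols = sum(max(len(e.ref_allele), len(e.alt_allele))
                         for e in events)
        identity = max(0.0, 1.0 - n_err_cols / max(1, len(seq)))
        q = int(round(identity_to_qscore(min(identity, 0.9999), q_cap=40)))
        quals = [max(2, q)] * len(seq)
        reads.append(SequenceRecord(read_id, seq, quals))
        ledgers[read_id] = ReadLedger(read_id, start, span, strand, events)
        total += len(seq)
        idx += 1
    return reads, ledgers


def _inside(start: int, span: int, pos: int, L: int) -> bool:
    """Is reference position ``pos`` within the read's covered span?"""
    return (pos - start) % L < span


def replay_read(truth: SimulationTruth, ledger: ReadLedger) -> str:
    """Reconstruct a read from the reference and its event ledger."""
    return _build_read(truth.reference.sequence, len(truth.reference.sequence),
                       ledger.start, ledger.ref_span, ledger.events,
                       ledger.strand)


def expected_profile(truth: SimulationTruth,
                     config: SimulationConfig) -> ErrorProfile:
    """Consensus-level error profile implied by majority voting.

    A systematic channel whose per-read rate exceeds one half wins the vote
    at each of its planted sites and contributes one consensus error of the
    matching class; random errors and sub-majority systematic ones
    contribute (approximately) nothing at depth of a few tens.
    """
    counts = {k: 0 for k in ALL_KLASSES}
    base_counts = {k: 0 for k in ALL_KLASSES}
    if config.dcm_error_rate > 0.5:
        counts[KLASS_DCM] = len(truth.motifs)
        base_counts[KLASS_DCM] = len(truth.motifs)
    if config.homopolymer_slip_rate > 0.5:
        for run in truth.runs:
            klass = KLASS_HP_INS if run.slip_direction > 0 else KLASS_HP_DEL
            counts[klass] += 1
            base_counts[klass] += 1
    L = config.genome_bp
    rates = {k: 100.0 * c / L for k, c in counts.items()}
    total_pct = 100.0 * sum(base_counts.values()) / L
    return ErrorProfile(counts, base_counts, rates, total_pct, L)


def write_truth_tsv(truth: SimulationTruth, path: str | Path) -> None:
    """Ledger export: one row per read with a compact event list."""
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tref_span\tstrand\tevents\n")
        for rid in sorted(truth.ledgers):
            led = truth.ledgers[rid]
            ev = ";".join(
                f"{e.ref_pos}:{e.kind[:3]}:{e.ref_allele or '.'}:"
                f"{e.alt_allele or '.'}:{e.channel}"
                for e in sorted(led.events, key=lambda e: e.ref_pos))
            fh.write(f"{rid}\t{led.start}\t{led.ref_span}\t{led.strand}\t"
                     f"{ev or '.'}\n")
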