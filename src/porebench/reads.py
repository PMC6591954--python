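"""Read-level accuracy: selection, per-read identity with edge rules, summaries.

The procedure mirrors standard nanopore basecaller benchmarking practice:
each read's BLAST identity (matches over all alignment columns) is taken
from its single best alignment to a trusted reference; a read with less
than half its length aligned scores 0%, as does a read the basecaller
failed to output at all (guarding against selective output inflating the
average).  A read set is summarised by the median identity over *all*
expected reads, expressed also as a Phred qscore.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, asdict
from pathlib import Path

from .align import Alignment, aligned_fraction, blast_identity
from .seqio import (SequenceRecord, identity_to_qscore, mean_read_quality,
                    DEFAULT_Q_CAP)

__all__ = [
    "ReadResult",
    "ReadSetSummary",
    "select_reads",
    "score_read",
    "missing_read_result",
    "summarize",
    "write_read_results_tsv",
]

STATUS_ALIGNED = "aligned"
STATUS_UNDER_HALF = "under_half_aligned"
STATUS_UNALIGNED = "unaligned"
STATUS_MISSING = "missing"


@dataclass(frozen=True)
class ReadResult:
    read_id: str
    length: int
    identity: float
    aligned_fraction: float
    status: str
    mean_quality: float | None = None

    def __post_init__(self):
        if self.status != STATUS_ALIGNED and self.identity != 0.0:
            raise ValueError(
                f"{self.status} read {self.read_id!r} must have identity 0")


@dataclass(frozen=True)
class ReadSetSummary:
    n_reads_expected: int
    n_reads_output: int
    median_identity: float
    read_qscore: float
    n50: int
    total_bases: int
    fraction_below_fail: float


def select_reads(alignments: dict[str, Alignment | None],
                 min_alignment_bp: int) -> set[str]:
    """Keep reads whose alignment spans >= ``min_alignment_bp`` of reference.

    This is the long-alignment selection filter used to exclude junk,
    improperly demultiplexed and short reads when assembling a benchmarking
    set; the threshold is genome- and depth-dependent, so it is a parameter.
    """
    if min_alignment_bp < 0:
        raise ValueError("min_alignment_bp must be >= 0")
    return {rid for rid, aln in alignments.items()
            if aln is not None and aln.ref_span >= min_alignment_bp}


def score_read(read: SequenceRecord, aln: Alignment | None) -> ReadResult:
    """Apply the per-read identity rules to one read.

    Identity is the alignment's BLAST identity when at least half the read
    aligned; reads under that bar (or entirely unaligned) score 0.
    """
    mean_q = mean_read_quality(read.qualities) if read.qualities else None
    frac = aligned_fraction(aln, len(read))
    if aln is None:
        return ReadResult(read.id, len(read), 0.0, 0.0, STATUS_UNALIGNED,
                          mean_q)
    if frac < 0.5:  # strictly "less than half"
        return ReadResult(read.id, len(read), 0.0, frac, STATUS_UNDER_HALF,
                          mean_q)
    return ReadResult(read.id, len(read), blast_identity(aln), frac,
                      STATUS_ALIGNED, mean_q)


def missing_read_result(read_id: str, length: int = 0) -> ReadResult:
    """Result for a read expected but absent from the basecaller output."""
    return ReadResult(read_id, length, 0.0, 0.0, STATUS_MISSING)


def _n50(lengths: list[int]) -> int:
    """Largest L such that reads of length >= L hold >= half of all bases."""
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    return 0


def summarize(results: list[ReadResult], fail_q: float = 7.0,
              q_cap: float = DEFAULT_Q_CAP) -> ReadSetSummary:
    """Summarise a read set: median identity (missing reads counted at 0),
    its qscore, N50, and the share of reads below the quality fail bar."""
    if not results:
        raise ValueError("no read results to summarise")
    identities = [r.identity for r in results]
    median = statistics.median(identities)
    lengths = [r.length for r in results if r.status != STATUS_MISSING]
    n_output = len(lengths)
    with_q = [r for r in results if r.mean_quality is not None]
    below = sum(1 for r in with_q if r.mean_quality < fail_q)
    frac_below = below / len(with_q) if with_q else 0.0
    return ReadSetSummary(
        n_reads_expected=len(results),
        n_reads_output=n_output,
        median_identity=median,
        read_qscore=identity_to_qscore(median, q_cap),
        n50=_n50(lengths),
        total_bases=sum(lengths),
        fraction_below_fail=frac_below,
    )


def write_read_results_tsv(results: list[ReadResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlength\taligned_fraction\tidentity\tstatus\n")
        for r in results:
            fh.write(f"{r.read_id}\t{r.length}\t{r.aligned_fraction:.6f}\t"
                     f"{r.identity:.6f}\t{r.status}\n")


def summary_to_json(summary: ReadSetSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
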