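"""Sequence records, FASTA/FASTQ I/O and Phred-scale conversions.

Conventions used throughout the package:

* sequences are uppercase strings over the alphabet ``{A, C, G, T, N}``
  (lowercase input is normalised on read, anything else is rejected);
* qualities are Phred integers, serialised as Phred+33 ASCII;
* identities live in ``[0, 1]`` and convert to qscores via
  ``q = -10 * log10(1 - identity)``, so Q10 = 90%, Q20 = 99%, Q30 = 99.9%.
"""

from __future__ import annotations

import gzip
import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SequenceRecord",
    "ParseError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "reverse_complement",
    "identity_to_qscore",
    "qscore_to_identity",
    "mean_read_quality",
    "enumerate_pore_states",
]

VALID_BASES = frozenset("ACGTN")
DEFAULT_Q_CAP = 90.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed FASTA/FASTQ input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}"
            )
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        quals = self.qualities[::-1] if self.qualities is not None else None
        return SequenceRecord(self.id, reverse_complement(self.sequence), quals)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_sequence(seq: str, line: int) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ParseError(f"invalid sequence characters {sorted(bad)!r}", line)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file.

    Multi-line sequences are concatenated; record order is preserved.
    Raises :class:`ParseError` with a line number on malformed input.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(parts)
        if not seq:
            raise ParseError(f"record {header!r} has an empty sequence", header_line)
        records.append(SequenceRecord(header, seq))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError("empty FASTA header", lineno)
                header_line = lineno
                parts = []
            else:
                if header is None:
                    raise ParseError(
                        "expected '>' header before sequence data", lineno
                    )
                parts.append(_clean_sequence(line, lineno))
        flush()
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line-per-record Phred+33 FASTQ (optionally gzipped)."""
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        lines = iter(enumerate(fh, 1))
        while True:
            try:
                lineno, head = next(lines)
            except StopIteration:
                break
            head = head.rstrip("\n")
            if not head.strip():
                continue
            if not head.startswith("@"):
                raise ParseError("expected '@' record header", lineno)
            name = head[1:].split()[0] if len(head) > 1 else ""
            if not name:
                raise ParseError("empty FASTQ header", lineno)
            try:
                seq_no, seq = next(lines)
                plus_no, plus = next(lines)
                qual_no, qual = next(lines)
            except StopIteration:
                raise ParseError(f"truncated record {name!r}", lineno) from None
            seq = _clean_sequence(seq.strip(), seq_no)
            if not plus.startswith("+"):
                raise ParseError("expected '+' separator", plus_no)
            qual = qual.strip()
            if len(qual) != len(seq):
                raise ParseError(
                    f"quality length {len(qual)} != sequence length {len(seq)}",
                    qual_no,
                )
            quals = [ord(c) - 33 for c in qual]
            if any(q < 0 for q in quals):
                raise ParseError("quality characters below Phred+33 '!'", qual_no)
            records.append(SequenceRecord(name, seq, quals))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(min(q, 93) + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; N maps to N."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def identity_to_qscore(identity: float, q_cap: float = DEFAULT_Q_CAP) -> float:
    """Convert a sequence identity to a Phred qscore.

    ``q = -10 * log10(1 - identity)``; a perfect identity of 1.0 returns
    ``q_cap`` so summaries of error-free runs stay finite.
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity {identity} outside [0, 1]")
    if q_cap <= 0:
        raise ValueError("q_cap must be positive")
    if identity >= 1.0:
        return float(q_cap)
    q = -10.0 * math.log10(1.0 - identity)
    return min(q, float(q_cap))


def qscore_to_identity(q: float) -> float:
    """Inverse of :func:`identity_to_qscore`: ``1 - 10**(-q/10)``."""
    if q < 0:
        raise ValueError(f"negative qscore {q}")
    return 1.0 - 10.0 ** (-q / 10.0)


def mean_read_quality(qualities: Sequence[int]) -> float:
    """Mean Phred quality of a read, averaged on the error-probability scale.

    Averaging raw Phred values overweights high-quality bases; the standard
    approach (used e.g. for the ONT Q7 pass/fail flag) averages per-base
    error probabilities and converts the mean back to the Phred scale.
    """
    if not qualities:
        raise ValueError("empty quality list")
    mean_err = sum(10.0 ** (-q / 10.0) for q in qualities) / len(qualities)
    return -10.0 * math.log10(mean_err)


def enumerate_pore_states(pore_width: int = 5,
                          alphabet: Sequence[str] = "ACGT") -> Iterator[tuple]:
    """Enumerate the k-mer states a pore of the given width can hold.

    The narrowest point of the R9.4 pore reads about five nucleotides at
    once, so a four-base model has 4**5 = 1024 states; adding a modified
    base such as 5-methylcytosine to the alphabet grows this to 5**5 = 3125.
    """
    if pore_width < 1:
        raise ValueError("pore_width must be >= 1")
    if len(set(alphabet)) != len(alphabet) or not alphabet:
        raise ValueError("alphabet must be non-empty and without duplicates")
    return itertools.product(alphabet, repeat=pore_width)


def count_pore_states(pore_width: int = 5, alphabet: Sequence[str] = "ACGT") -> int:
    """Number of distinct pore k-mer states, by explicit enumeration."""
    return sum(1 for _ in enumerate_pore_states(pore_width, alphabet))
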