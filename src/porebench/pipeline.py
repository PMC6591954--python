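"""End-to-end orchestration: simulate a read set, evaluate a read set.

``evaluate`` runs the full accuracy assessment on a read set against a
single-contig reference: map reads, apply the per-read identity rules,
build the iterative reference-guided consensus, measure chunked consensus
identity, and classify every consensus error by reference context.  The
result is a :class:`RunReport` bundling the read summary, the consensus
summary and the error profile, with provenance (seed, config hash, tool
version) for reproducibility: the report JSON is bitwise identical for
fixed inputs and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .align import ReferenceIndex, map_read, align_global
from .consensus import ConsensusParams, IterativeResult, iterative_consensus
from .errors import (ConsensusSummary, ErrorProfile, ErrorEvent,
                     chunk_assembly, classify_error, consensus_identity,
                     error_profile, extract_errors, find_homopolymers,
                     find_motif_sites, write_errors_tsv, profile_to_json)
from .reads import (ReadResult, ReadSetSummary, score_read, select_reads,
                    summarize, missing_read_result, write_read_results_tsv)
from .seqio import (SequenceRecord, read_fasta, read_fastq, write_fasta,
                    write_fastq, DEFAULT_Q_CAP)
from .simulate import (SimulationConfig, SimulationTruth, generate_reference,
                       simulate_reads, write_truth_tsv)

__all__ = ["RunReport", "evaluate", "run_evaluate", "run_simulate",
           "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """All summary surfaces of one evaluation run."""

    read_summary: ReadSetSummary
    consensus_summary: ConsensusSummary | None
    profile: ErrorProfile | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "read_summary": dataclasses.asdict(self.read_summary),
            "consensus_summary": dataclasses.asdict(self.consensus_summary)
            if self.consensus_summary else None,
            "profile": dataclasses.asdict(self.profile)
            if self.profile else None,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _provenance(seed: int, options: dict) -> dict:
    blob = json.dumps(options, sort_keys=True).encode()
    return {
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
        "tool_version": __version__,
    }


def profile_assembly(assembly: SequenceRecord, reference: SequenceRecord
                     ) -> tuple[list[ErrorEvent], ErrorProfile]:
    """Align an assembly to its reference and classify every difference."""
    aln = align_global(assembly, reference)
    motif_sites = find_motif_sites(reference)
    runs = find_homopolymers(reference)
    events = [classify_error(e, motif_sites, runs)
              for e in extract_errors(aln, assembly, reference)]
    return events, error_profile(events, len(reference.sequence))


def evaluate(reads: list[SequenceRecord], reference: SequenceRecord, *,
             params: ConsensusParams | None = None,
             min_align_bp: int = 0, fail_q: float = 7.0,
             expected_read_ids: set[str] | None = None,
             circular: bool = True, chunk_bp: int = 10_000,
             skip_consensus: bool = False,
             q_cap: float = DEFAULT_Q_CAP,
             ) -> tuple[RunReport, IterativeResult | None,
                        list[ReadResult], list[ErrorEvent]]:
    """Run the full read + consensus accuracy assessment.

    ``expected_read_ids`` lets the caller declare reads the basecaller was
    supposed to output; any that are absent from ``reads`` are scored at 0%
    identity so selective output cannot inflate the median.  When
    ``min_align_bp`` is positive, the alignment-length selection filter is
    applied first and all downstream metrics use the selected set.
    """
    if params is None:
        params = ConsensusParams()
    options = {
        "min_align_bp": min_align_bp, "fail_q": fail_q, "circular": circular,
        "chunk_bp": chunk_bp, "skip_consensus": skip_consensus,
        "iterations": params.iterations, "polish_rounds": params.polish_rounds,
        "q_cap": q_cap,
    }
    index = ReferenceIndex(reference, circular=circular)
    logger.info("mapping %d reads", len(reads))
    alignments = {r.id: map_read(r, index, backend=params.backend)
                  for r in reads}
    if min_align_bp > 0:
        keep = select_reads(alignments, min_align_bp)
        logger.info("selection: %d/%d reads with >= %d bp alignment",
                    len(keep), len(reads), min_align_bp)
        reads = [r for r in reads if r.id in keep]
    results = [score_read(r, alignments[r.id]) for r in reads]
    present = {r.id for r in reads}
    for rid in sorted(expected_read_ids or set()):
        if rid not in present:
            results.append(missing_read_result(rid))
    read_summary = summarize(results, fail_q, q_cap)

    aligned = [r for r in reads if alignments[r.id] is not None]
    consensus_summary = None
    profile = None
    events: list[ErrorEvent] = []
    iterative: IterativeResult | None = None
    if not skip_consensus:
        if not aligned:
            logger.warning("no alignable reads: consensus accuracy is 0")
            consensus_summary = ConsensusSummary(0.0, 0.0, 0.0, 0)
            profile = error_profile([], len(reference.sequence))
        else:
            logger.info("building iterative consensus (%d iterations)",
                        params.iterations)
            iterative = iterative_consensus(reference, aligned, params,
                                            circular=circular)
            chunks = chunk_assembly(iterative.assembly, chunk_bp)
            consensus_summary = consensus_identity(chunks, reference,
                                                   circular=circular,
                                                   q_cap=q_cap)
            events, profile = profile_assembly(iterative.assembly, reference)
    report = RunReport(read_summary, consensus_summary, profile,
                       _provenance(params.seed, options))
    return report, iterative, results, events


def run_evaluate(reads_path: str | Path, reference_path: str | Path,
                 outdir: str | Path, **kwargs) -> RunReport:
    """File-level wrapper around :func:`evaluate`; writes all side files."""
    reads_path = Path(reads_path)
    if reads_path.name.endswith((".fastq", ".fastq.gz", ".fq", ".fq.gz")):
        reads = read_fastq(reads_path)
    else:
        reads = read_fasta(reads_path)
    refs = read_fasta(reference_path)
    if len(refs) != 1:
        raise ValueError(
            f"reference must be a single contig, got {len(refs)} records "
            "(multi-contig references are not supported)")
    reference = refs[0]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report, iterative, results, events = evaluate(reads, reference, **kwargs)
    write_read_results_tsv(results, outdir / "reads.tsv")
    if iterative is not None:
        write_fasta([iterative.assembly], outdir / "assembly.fasta")
    if report.profile is not None:
        write_errors_tsv(events, reference.id, outdir / "errors.tsv")
        profile_to_json(report.profile, outdir / "profile.json")
    report.to_json(outdir / "report.json")
    logger.info("report written to %s", outdir / "report.json")
    return report


def load_config(path: str | Path) -> SimulationConfig:
    """Parse a simulation config YAML, with field-naming validation errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    if "homopolymer_spec" in data:
        data["homopolymer_spec"] = tuple(
            tuple(item) for item in data["homopolymer_spec"])
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return SimulationConfig(**data)


def run_simulate(config: SimulationConfig | str | Path,
                 outdir: str | Path) -> SimulationTruth:
    """Generate a reference + read set and write all artefacts.

    Writes ``reference.fasta``, ``reads.fastq``, ``truth.tsv`` and a
    ``config.yaml`` snapshot; identical config and seed give identical
    files.
    """
    if not isinstance(config, SimulationConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_reference(config)
    reads, ledgers = simulate_reads(truth, config)
    truth.ledgers = ledgers
    write_fasta([truth.reference], outdir / "reference.fasta")
    write_fastq(reads, outdir / "reads.fastq")
    write_truth_tsv(truth, outdir / "truth.tsv")
    snapshot = dataclasses.asdict(config)
    snapshot["homopolymer_spec"] = [list(x)
                                    for x in snapshot["homopolymer_spec"]]
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=True)
    logger.info("simulated %d reads over a %d bp reference into %s",
                len(reads), config.genome_bp, outdir)
    return truth
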