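"""Chunking, consensus identity and the error taxonomy."""

import numpy as np
import pytest

from porebench.align import Alignment, AlignOp, ReferenceIndex, blast_identity, map_read
from porebench.errors import (ErrorEvent, chunk_assembly,
                              classify_error, consensus_identity,
                              error_profile, extract_errors,
                              find_homopolymers, find_motif_sites)
from porebench.pipeline import profile_assembly
from porebench.seqio import SequenceRecord

BASES = "ACGT"


def _random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


class TestChunkAssembly:
    @pytest.mark.parametrize("length,expected_sizes", [
        (25_000, [10_000, 10_000, 5_000]),   # tail of exactly chunk/2 kept
        (24_000, [10_000, 14_000]),          # short tail merged into previous
        (20_000, [10_000, 10_000]),
        (9_000, [9_000]),                    # shorter than one chunk
    ])
    def test_piece_sizes(self, length, expected_sizes):
        rng = np.random.default_rng(1)
        asm = SequenceRecord("a", _random_seq(rng, length))
        chunks = chunk_assembly(asm, 10_000)
        assert [len(c) for c in chunks] == expected_sizes
        assert "".join(c.sequence for c in chunks) == asm.sequence

    def test_minimum_chunk_size_enforced(self):
        with pytest.raises(ValueError):
            chunk_assembly(SequenceRecord("a", "ACGT" * 300), 500)


class TestConsensusIdentity:
    def test_assembly_equals_reference(self):
        rng = np.random.default_rng(2)
        ref = SequenceRecord("ref", _random_seq(rng, 25_000))
        asm = SequenceRecord("asm", ref.sequence)
        summary = consensus_identity(chunk_assembly(asm), ref, q_cap=90)
        assert summary.median_chunk_identity == 1.0
        assert summary.consensus_qscore == 90.0
        assert summary.chunk_identity_sd == 0.0
        assert summary.n_chunks == 3

    def test_one_substitution_per_chunk(self):
        rng = np.random.default_rng(3)
        ref = SequenceRecord("ref", _random_seq(rng, 20_000))
        seq = list(ref.sequence)
        for pos in (5_000, 15_000):
            seq[pos] = BASES[(BASES.index(seq[pos]) + 1) % 4]
        summary = consensus_identity(
            chunk_assembly(SequenceRecord("asm", "".join(seq))), ref)
        assert summary.median_chunk_identity == pytest.approx(0.9999)

    def test_qscore_of_9933_identity(self):
        # a 99.33%-identity consensus corresponds to Q21.74
        rng = np.random.default_rng(4)
        ref = SequenceRecord("ref", _random_seq(rng, 10_000))
        seq = list(ref.sequence)
        rng2 = np.random.default_rng(5)
        for pos in rng2.choice(10_000, size=67, replace=False):
            seq[pos] = BASES[(BASES.index(seq[pos]) + 1) % 4]
        summary = consensus_identity(
            chunk_assembly(SequenceRecord("asm", "".join(seq))), ref)
        # co-optimal alignments may trade a substitution for an indel pair,
        # shifting identity by ~1e-6; the conversion itself is exact
        assert summary.median_chunk_identity == pytest.approx(0.9933, abs=5e-6)
        assert summary.consensus_qscore == pytest.approx(21.74, abs=0.01)


class TestMotifSites:
    def test_single_occurrence_interval(self):
        sites = find_motif_sites(SequenceRecord("r", "AACCAGGTT"))
        assert sites.intervals == [(2, 7)]
        assert 2 in sites and 6 in sites and 7 not in sites and 1 not in sites

    def test_reverse_complement_motif_found_on_forward_scan(self):
        sites = find_motif_sites(SequenceRecord("r", "TTCCTGGAA"))
        assert sites.intervals == [(2, 7)]

    def test_motif_free_sequence(self):
        assert len(find_motif_sites(SequenceRecord("r", "ACGTACGTACGT"))) == 0

    def test_overlapping_occurrences_unioned(self):
        sites = find_motif_sites(SequenceRecord("r", "CCAGGCCTGG"))
        assert sites.intervals == [(0, 10)]


class TestHomopolymers:
    def test_basic_run(self):
        runs = list(find_homopolymers(SequenceRecord("r", "ACCCGT"), 3))
        assert [(r.start, r.length, r.base) for r in runs] == [(1, 3, "C")]

    def test_maximality(self):
        runs = list(find_homopolymers(SequenceRecord("r", "AAAAA"), 3))
        assert [(r.start, r.length, r.base) for r in runs] == [(0, 5, "A")]

    def test_no_runs(self):
        assert len(find_homopolymers(SequenceRecord("r", "ACGTACGT"), 3)) == 0


class TestExtractErrors:
    def test_perfect_alignment_gives_no_events(self):
        ref = SequenceRecord("ref", "ACGTACGTAC")
        aln = Alignment("q", "ref", 0, 10, 0, 10, "+", [AlignOp("match", 10)])
        assert extract_errors(aln, SequenceRecord("q", ref.sequence), ref) == []

    def test_mismatch_run_split_per_base(self):
        ref = SequenceRecord("ref", "AAATTAAA")
        qry = SequenceRecord("q", "AAACCAAA")
        aln = Alignment("q", "ref", 0, 8, 0, 8, "+",
                        [AlignOp("match", 3), AlignOp("mismatch", 2),
                         AlignOp("match", 3)])
        events = extract_errors(aln, qry, ref)
        assert [(e.ref_pos, e.kind, e.ref_allele, e.alt_allele)
                for e in events] == [(3, "substitution", "T", "C"),
                                     (4, "substitution", "T", "C")]

    def test_deletion_run_single_event_with_full_allele(self):
        ref = SequenceRecord("ref", "AAAACGTTTT")
        qry = SequenceRecord("q", "AAAATTTT")
        aln = Alignment("q", "ref", 0, 10, 0, 8, "+",
                        [AlignOp("match", 4), AlignOp("deletion", 2),
                         AlignOp("match", 4)])
        events = extract_errors(aln, qry, ref)
        assert len(events) == 1
        e = events[0]
        assert (e.ref_pos, e.kind, e.ref_allele) == (4, "deletion", "CG")

    def test_insertion_positioned_right_of_junction(self):
        ref = SequenceRecord("ref", "AAAATTTT")
        aln = Alignment("q", "ref", 0, 8, 0, 10, "+",
                        [AlignOp("match", 4), AlignOp("insertion", 2),
                         AlignOp("match", 4)])
        e = extract_errors(aln, SequenceRecord("q", "AAAACGTTTT"), ref)[0]
        assert (e.ref_pos, e.kind, e.alt_allele) == (4, "insertion", "CG")


class TestClassify:
    @pytest.fixture()
    def context(self):
        ref = SequenceRecord("ref", "AACCAGGTTCCCCGTACGTACGT")
        return find_motif_sites(ref), find_homopolymers(ref)

    def test_substitution_in_motif_is_dcm(self, context):
        sites, runs = context
        e = classify_error(ErrorEvent(3, "substitution", "C", "T"),
                           sites, runs)
        assert e.klass == "dcm"

    def test_deletion_in_homopolymer(self, context):
        sites, runs = context
        e = classify_error(ErrorEvent(10, "deletion", "C", ""), sites, runs)
        assert e.klass == "homopolymer_deletion"

    def test_insertion_adjacent_to_run_both_flanks(self, context):
        sites, runs = context
        # junction right-neighbour at run start (left flank of run)
        left = classify_error(ErrorEvent(9, "insertion", "", "C"), sites, runs)
        # junction right-neighbour just past run end (right flank)
        right = classify_error(ErrorEvent(13, "insertion", "", "C"),
                               sites, runs)
        assert left.klass == right.klass == "homopolymer_insertion"

    def test_plain_kinds_when_no_context_applies(self, context):
        sites, runs = context
        assert classify_error(ErrorEvent(17, "substitution", "A", "C"),
                              sites, runs).klass == "substitution"
        assert classify_error(ErrorEvent(17, "deletion", "AC", ""),
                              sites, runs).klass == "deletion"
        assert classify_error(ErrorEvent(17, "insertion", "", "AC"),
                              sites, runs).klass == "insertion"

    def test_dcm_takes_precedence_over_homopolymer(self):
        # a deletion that both touches a motif and lies in a run: Dcm wins
        ref = SequenceRecord("ref", "ACCCAGGGGTA")
        sites = find_motif_sites(ref)
        runs = find_homopolymers(ref)
        e = classify_error(ErrorEvent(6, "deletion", "G", ""), sites, runs)
        assert e.klass == "dcm"

    def test_mixed_base_insertion_never_homopolymeric(self, context):
        sites, runs = context
        e = classify_error(ErrorEvent(10, "insertion", "", "CA"), sites, runs)
        assert e.klass == "insertion"


class TestErrorProfile:
    def test_empty_profile(self):
        p = error_profile([], 10_000)
        assert p.total_events == 0 and p.total_error_pct == 0.0

    def test_rates_arithmetic(self):
        events = [ErrorEvent(i, "substitution", "A", "C", klass="dcm")
                  for i in range(5)]
        p = error_profile(events, 10_000)
        assert p.rates_per_100bp["dcm"] == pytest.approx(0.05)
        assert p.total_error_pct == pytest.approx(0.05)

    def test_counts_sum_equals_events(self):
        events = [
            ErrorEvent(1, "substitution", "A", "C", klass="dcm"),
            ErrorEvent(2, "deletion", "AA", "", klass="homopolymer_deletion"),
            ErrorEvent(3, "insertion", "", "T", klass="insertion"),
        ]
        p = error_profile(events, 1000)
        assert p.total_events == len(events)
        assert sum(p.counts.values()) == len(events)
        assert p.base_counts["homopolymer_deletion"] == 2

    def test_unclassified_events_rejected(self):
        with pytest.raises(ValueError):
            error_profile([ErrorEvent(1, "substitution", "A", "C")], 100)


class TestEndToEndInvariants:
    def test_identity_consistency_on_simulated_read(self, random_error_sim):
        """1 - (error bases / columns) equals BLAST identity exactly."""
        _, truth, reads = random_error_sim
        index = ReferenceIndex(truth.reference, circular=True)
        for read in reads[:20]:
            aln = map_read(read, index)
            events = extract_errors(aln, read, truth.reference)
            err_cols = sum(e.length for e in events)
            assert 1 - err_cols / aln.n_columns == pytest.approx(
                blast_identity(aln), abs=1e-9)

    def test_partition_every_event_classified_once(self, systematic_sim,
                                                   systematic_consensus):
        _, truth, _ = systematic_sim
        events, profile = profile_assembly(systematic_consensus.assembly,
                                           truth.reference)
        assert all(e.klass is not None for e in events)
        assert sum(profile.counts.values()) == len(events)

    def test_dcm_classification_complete_and_exclusive(self, systematic_sim,
                                                       systematic_consensus):
        """Planted-motif consensus substitutions are all Dcm; nothing outside
        a motif interval is called Dcm."""
        _, truth, _ = systematic_sim
        events, _ = profile_assembly(systematic_consensus.assembly,
                                     truth.reference)
        sites = find_motif_sites(truth.reference)
        planted = {m.start + m.miscall_offset for m in truth.motifs}
        sub_positions = {e.ref_pos for e in events
                         if e.kind == "substitution" and e.klass == "dcm"}
        assert planted <= sub_positions  # completeness at 90% per-read rate
        for e in events:
            if e.klass == "dcm":
                assert e.ref_pos in sites or any(
                    (e.ref_pos + k) in sites
                    for k in range(len(e.ref_allele)))
            else:
                if e.kind == "substitution":
                    assert e.ref_pos not in sites

    def test_chunk_identity_sd_small_under_uniform_error(
            self, random_error_sim, random_error_consensus):
        """Uniform random error polishes to chunks with sd < 0.1 points."""
        _, truth, _ = random_error_sim
        summary = consensus_identity(
            chunk_assembly(random_error_consensus.assembly),
            truth.reference, circular=True)
        assert summary.chunk_identity_sd * 100 < 0.1
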