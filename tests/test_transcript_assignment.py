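"""Splice-fidelity rules and read-to-transcript assignment."""

import pytest

from haplotx.io_formats import GenomeInterval, TranscriptModel
from haplotx.transcript_assignment import (
    FidelityConfig,
    assign_reads,
    check_splice,
    check_stringent,
    select_best_transcript_alignments,
    supported_annotated_isoforms,
)

from conftest import make_aln, single_exon_transcript

CFG = FidelityConfig()


def full_span_read(n_match: int, n_mismatch: int, start: int = 0):
    segs = []
    if n_match:
        segs.append(("match", n_match))
    if n_mismatch:
        segs.append(("mismatch", n_mismatch))
    return make_aln(segs, start=start)


class TestStringentTruthTable:
    """One factor perturbed at a time around each threshold."""

    @pytest.mark.parametrize(
        "matches,expected",
        [(79, False), (80, True), (81, True)],
    )
    def test_identity_boundary(self, matches, expected):
        tx = single_exon_transcript(100)
        aln = full_span_read(matches, 100 - matches)
        exon = tx.exons[0]
        assert check_stringent(aln, 100, exon, exon, CFG) is expected

    @pytest.mark.parametrize(
        "missed,expected",
        [(24, True), (25, True), (26, False)],
    )
    def test_end_span_boundary_5p(self, missed, expected):
        tx = single_exon_transcript(600)
        aln = make_aln([("match", 600 - missed)], start=missed)
        exon = tx.exons[0]
        assert check_stringent(aln, 600, exon, exon, CFG) is expected

    @pytest.mark.parametrize(
        "missed,expected",
        [(24, True), (25, True), (26, False)],
    )
    def test_end_span_boundary_3p(self, missed, expected):
        tx = single_exon_transcript(600)
        aln = make_aln([("match", 600 - missed)], start=0)
        exon = tx.exons[0]
        assert check_stringent(aln, 600, exon, exon, CFG) is expected

    def test_short_terminal_exon_allowance_capped(self):
        # 10 bp first exon: the whole exon may be missed, no more
        tx = TranscriptModel(
            "t",
            "g",
            [GenomeInterval("c", 0, 10, "+"), GenomeInterval("c", 50, 640, "+")],
        )
        first, last = tx.exons_in_transcript_order()[0], tx.exons_in_transcript_order()[-1]
        ok = make_aln([("match", 590)], start=10)
        bad = make_aln([("match", 589)], start=11)
        assert check_stringent(ok, 600, first, last, CFG)
        assert not check_stringent(bad, 600, first, last, CFG)

    def test_inconsistent_transcript_length_raises(self):
        exon = GenomeInterval("c", 0, 700, "+")
        with pytest.raises(ValueError):
            check_stringent(make_aln([("match", 100)]), 600, exon, exon, CFG)


class TestSpliceTruthTable:
    # junction at transcript offset 300 of a 600 bp transcript

    @pytest.mark.parametrize(
        "n_mismatch,expected",
        [(1, True), (2, True), (3, False)],
    )
    def test_flank_match_boundary(self, n_mismatch, expected):
        aln = make_aln(
            [
                ("match", 297),
                ("mismatch", n_mismatch),
                ("match", 600 - 297 - n_mismatch),
            ]
        )
        assert check_splice(aln, [300], CFG) is expected

    @pytest.mark.parametrize(
        "del_len,expected",
        [(3, True), (4, False)],
    )
    def test_splice_indel_boundary(self, del_len, expected):
        # deletion starts at 302: overlaps the window by 1 bp, leaving
        # 5 matched window bases either way
        aln = make_aln(
            [("match", 302), ("deletion", del_len), ("match", 600 - 302 - del_len)]
        )
        assert check_splice(aln, [300], CFG) is expected

    @pytest.mark.parametrize(
        "ins_len,expected",
        [(3, True), (4, False)],
    )
    def test_splice_insertion_boundary(self, ins_len, expected):
        aln = make_aln(
            [("match", 300), ("insertion", ins_len), ("match", 300)]
        )
        assert check_splice(aln, [300], CFG) is expected

    def test_deletion_eating_window_matches_fails(self):
        # 3 bp deletion inside the window removes 3 matched bases: only 3 left
        aln = make_aln([("match", 298), ("deletion", 3), ("match", 299)])
        assert not check_splice(aln, [300], CFG)

    def test_uncovered_junction_imposes_no_constraint(self):
        # truncated read ends before the junction window
        aln = make_aln([("match", 290)])
        assert check_splice(aln, [300], CFG)
        # read covering only half the window is likewise unconstrained
        aln2 = make_aln([("match", 300)])
        assert check_splice(aln2, [300], CFG)

    def test_every_covered_junction_checked(self):
        aln = make_aln(
            [("match", 297), ("mismatch", 3), ("match", 600 - 300)]
        )
        assert not check_splice(aln, [100, 300, 500], CFG)
        clean = make_aln([("match", 600)])
        assert check_splice(clean, [100, 300, 500], CFG)


class TestCandidateSelection:
    def test_mapq_ordering(self):
        a_hi = make_aln([("match", 50)], chrom="t1", mapq=60)
        a_lo = make_aln([("match", 50)], chrom="t2", mapq=0)
        cands = select_best_transcript_alignments([a_lo, a_hi])
        assert [a.target_id for a in cands["r1"]] == ["t1", "t2"]

    def test_tie_break_by_edit_distance_then_id(self):
        worse = make_aln([("match", 45), ("mismatch", 5)], chrom="t1", mapq=60)
        better = make_aln([("match", 47), ("mismatch", 3)], chrom="t2", mapq=60)
        cands = select_best_transcript_alignments([worse, better])
        assert [a.target_id for a in cands["r1"]] == ["t2", "t1"]
        tie1 = make_aln([("match", 50)], chrom="tb", mapq=60)
        tie2 = make_aln([("match", 50)], chrom="ta", mapq=60)
        cands = select_best_transcript_alignments([tie1, tie2])
        assert [a.target_id for a in cands["r1"]] == ["ta", "tb"]

    def test_genome_alignment_rejected(self):
        with pytest.raises(ValueError):
            select_best_transcript_alignments(
                [make_aln([("match", 10)], target_kind="genome")]
            )


class TestAssignReads:
    @pytest.fixture
    def transcripts(self):
        return {
            "t1": TranscriptModel(
                "t1",
                "g",
                [GenomeInterval("c", 0, 300, "+"), GenomeInterval("c", 500, 800, "+")],
            ),
            "t2": TranscriptModel(
                "t2",
                "g",
                [GenomeInterval("c", 0, 300, "+"), GenomeInterval("c", 600, 900, "+")],
            ),
        }

    def test_second_candidate_rescues_failed_splice(self, transcripts):
        fail_t1 = make_aln(
            [("match", 297), ("mismatch", 3), ("match", 300)], chrom="t1"
        )
        pass_t2 = make_aln([("match", 600)], chrom="t2")
        assignments, unassigned = assign_reads(
            {"r1": [fail_t1, pass_t2]}, transcripts, CFG
        )
        assert assignments[0].transcript_id == "t2"
        assert not unassigned

    def test_read_failing_everywhere_is_unassigned(self, transcripts):
        bad = make_aln([("match", 100), ("mismatch", 500)], chrom="t1")
        assignments, unassigned = assign_reads({"r1": [bad]}, transcripts, CFG)
        assert not assignments
        assert unassigned == {"r1"}

    def test_assignment_partitions_reads(self, transcripts):
        good = make_aln([("match", 600)], chrom="t1", read_id="a")
        bad = make_aln([("mismatch", 600)], chrom="t1", read_id="b")
        assignments, unassigned = assign_reads(
            {"a": [good], "b": [bad], "c": []}, transcripts, CFG
        )
        assigned_ids = {x.read_id for x in assignments}
        assert assigned_ids | unassigned == {"a", "b", "c"}
        assert not assigned_ids & unassigned

    def test_monotonicity_in_identity_threshold(self, transcripts):
        reads = {
            f"r{i}": [
                make_aln(
                    [("match", 600 - i * 30), ("mismatch", i * 30)], chrom="t1",
                    read_id=f"r{i}",
                )
            ]
            for i in range(6)
        }
        n_assigned = []
        for min_id in (0.80, 0.90, 0.95):
            cfg = FidelityConfig(min_identity=min_id)
            a, _ = assign_reads(reads, transcripts, cfg)
            n_assigned.append(len(a))
        assert n_assigned == sorted(n_assigned, reverse=True)


class TestSupportFilter:
    def test_min_support_inclusive(self):
        from haplotx.transcript_assignment import ReadAssignment

        tx = {"t1": single_exon_transcript(100, "t1")}
        asn = [ReadAssignment(f"r{i}", "t1", True, True) for i in range(3)]
        kept = supported_annotated_isoforms(asn, tx, CFG)
        assert len(kept) == 1
        assert len(kept[0][1]) == 3

    def test_below_support_dropped(self):
        from haplotx.transcript_assignment import ReadAssignment

        tx = {"t1": single_exon_transcript(100, "t1")}
        asn = [ReadAssignment(f"r{i}", "t1", True, True) for i in range(2)]
        assert supported_annotated_isoforms(asn, tx, CFG) == []
        assert supported_annotated_isoforms([], tx, CFG) == []


def test_error_free_reads_all_pass():
    """Perfect reads from annotated transcripts pass both fidelity rules."""
    from haplotx.io_formats import read_alignments, transcript_sequence
    from haplotx.synthetic_data import (
        SimConfig,
        simulate_reads,
        simulate_reference,
        write_alignments,
    )
    import tempfile
    from pathlib import Path

    cfg = SimConfig(seed=2, n_genes=3, error_rate=0.0, truncation_prob=0.0,
                    reads_per_transcript=5)
    ref = simulate_reference(cfg)
    reads = simulate_reads(cfg, ref)
    with tempfile.TemporaryDirectory() as td:
        g, t = Path(td) / "g.sam", Path(td) / "t.sam"
        write_alignments(reads, ref, g, t)
        models = ref.models_by_id()
        tx_ref = {k: transcript_sequence(ref.genome, m) for k, m in models.items()}
        alns = list(read_alignments(t, "transcript", reference=tx_ref))
    cands = select_best_transcript_alignments(alns)
    assignments, unassigned = assign_reads(cands, models, CFG)
    assert not unassigned
    assert len(assignments) == len(reads)
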