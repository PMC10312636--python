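"""Splice-site correction, junction-chain grouping, end calling and the
final merge of novel with annotated isoforms."""

import pytest

from haplotx.io_formats import GenomeInterval, TranscriptModel
from haplotx.isoform_collapse import (
    CorrectedRead,
    FirstPassIsoform,
    JunctionEvidence,
    SpliceEvidence,
    assign_to_firstpass,
    build_firstpass,
    call_ends,
    correct_splice_sites,
    finalize,
    group_by_junction_chain,
)
from haplotx.transcript_assignment import FidelityConfig

from conftest import make_aln

CFG = FidelityConfig()


def evidence_from_pairs(pairs, chrom="chr1"):
    return SpliceEvidence(
        [JunctionEvidence(chrom, d, a, "+", "annotation") for d, a in pairs]
    )


def genome_read(read_id, start, segments):
    return make_aln(
        segments,
        start=start,
        chrom="chr1",
        target_kind="genome",
        read_id=read_id,
    )


class TestCorrection:
    def test_nearest_within_window(self):
        ev = evidence_from_pairs([(1000, 2000)])
        read = genome_read("r1", 900, [("match", 103), ("intron", 997), ("match", 100)])
        assert read.junctions() == ((1003, 2000),)
        corrected, flagged = correct_splice_sites([read], ev, window=10)
        assert not flagged
        assert corrected[0].junctions == ((1000, 2000),)

    def test_tie_breaks_to_smaller_coordinate(self):
        ev = SpliceEvidence(
            [
                JunctionEvidence("chr1", 1000, 2000, "+", "annotation"),
                JunctionEvidence("chr1", 1006, 2000, "+", "annotation"),
            ]
        )
        read = genome_read("r1", 900, [("match", 103), ("intron", 997), ("match", 100)])
        corrected, _ = correct_splice_sites([read], ev, window=10)
        assert corrected[0].junctions[0][0] == 1000

    def test_no_evidence_in_window_flags_read(self):
        ev = evidence_from_pairs([(1000, 2000)])
        read = genome_read("r1", 900, [("match", 120), ("intron", 980), ("match", 100)])
        assert read.junctions() == ((1020, 2000),)
        corrected, flagged = correct_splice_sites([read], ev, window=10)
        assert flagged == {"r1"}
        assert not corrected

    def test_long_read_evidence_needs_min_support(self):
        reads = [
            genome_read(f"r{i}", 900, [("match", 100), ("intron", 1000), ("match", 100)])
            for i in range(3)
        ]
        from haplotx.isoform_collapse import evidence_from_reads

        ev_weak = SpliceEvidence(evidence_from_reads(reads[:2]), min_long_read_support=3)
        assert ev_weak.nearest("chr1", "donor", 1000, 10) is None
        ev_strong = SpliceEvidence(evidence_from_reads(reads), min_long_read_support=3)
        assert ev_strong.nearest("chr1", "donor", 1000, 10) == 1000


class TestGrouping:
    def _cr(self, rid, junctions, start=0, end=5000):
        return CorrectedRead(rid, "chr1", "+", start, end, tuple(junctions))

    def test_identical_chains_one_group(self):
        j = [(100, 200), (300, 400), (500, 600)]
        groups = group_by_junction_chain([self._cr("a", j), self._cr("b", j)])
        assert len(groups) == 1
        (members,) = groups.values()
        assert {r.read_id for r in members} == {"a", "b"}

    def test_different_acceptor_two_groups(self):
        g = group_by_junction_chain(
            [self._cr("a", [(100, 200)]), self._cr("b", [(100, 210)])]
        )
        assert len(g) == 2

    def test_prefix_chain_is_separate_group(self):
        g = group_by_junction_chain(
            [
                self._cr("a", [(100, 200), (300, 400)]),
                self._cr("b", [(100, 200)]),
            ]
        )
        assert len(g) == 2

    def test_mono_exon_loci_by_overlap(self):
        g = group_by_junction_chain(
            [
                self._cr("a", [], 0, 500),
                self._cr("b", [], 400, 900),
                self._cr("c", [], 2000, 2500),
            ]
        )
        sizes = sorted(len(v) for v in g.values())
        assert sizes == [1, 2]


class TestCallEnds:
    def _cr(self, rid, start, end):
        return CorrectedRead(rid, "chr1", "+", start, end, ())

    def test_close_starts_one_cluster(self):
        out = call_ends(
            [self._cr("a", 1000, 3000), self._cr("b", 1005, 3000), self._cr("c", 1007, 3000)]
        )
        assert len(out) == 1

    def test_distant_starts_two_isoforms(self):
        out = call_ends([self._cr("a", 1000, 3000), self._cr("b", 1500, 3000)])
        assert len(out) == 2
        assert sorted(t[0] for t in out) == [1000, 1500]

    def test_single_read_keeps_its_ends(self):
        out = call_ends([self._cr("a", 1234, 4321)])
        assert out == [(1234, 4321, {"a"})]

    def test_representative_is_mode_with_outermost_ties(self):
        reads = [
            self._cr("a", 1000, 3000),
            self._cr("b", 1000, 3050),
            self._cr("c", 1010, 3050),
        ]
        ((tss, tes, ids),) = call_ends(reads)
        assert tss == 1000  # mode
        assert tes == 3050  # mode; tie would go outermost (max)


def _make_genome_with_intron(donor, acceptor, length=3000, strand="+"):
    seq = list("A" * length)
    if strand == "+":
        seq[donor : donor + 2] = "GT"
        seq[acceptor - 2 : acceptor] = "AG"
    else:
        seq[donor : donor + 2] = "CT"
        seq[acceptor - 2 : acceptor] = "AC"
    return {"chr1": "".join(seq)}


class TestBuildFirstpass:
    def test_strand_inferred_from_dinucleotides(self):
        for strand in "+-":
            genome = _make_genome_with_intron(500, 900, strand=strand)
            reads = [
                CorrectedRead(f"r{i}", "chr1", "+", 100, 1400, ((500, 900),))
                for i in range(3)
            ]
            (fp,) = build_firstpass(group_by_junction_chain(reads), genome)
            assert fp.model.strand == strand
            assert [(e.start, e.end) for e in fp.model.exons] == [
                (100, 500),
                (900, 1400),
            ]


class TestAssignToFirstpass:
    @pytest.fixture
    def setup(self):
        genome = _make_genome_with_intron(500, 900)
        full_reads = [
            genome_read(f"f{i}", 100, [("match", 400), ("intron", 400), ("match", 500)])
            for i in range(4)
        ]
        ev = evidence_from_pairs([(500, 900)])
        corrected, _ = correct_splice_sites(full_reads, ev)
        groups = group_by_junction_chain(corrected)
        firstpass = build_firstpass(groups, genome)
        return genome, full_reads, corrected, firstpass

    def test_reads_reassign_to_their_own_model(self, setup):
        _genome, reads, corrected, firstpass = setup
        supports, unassigned, moved = assign_to_firstpass(
            reads, {c.read_id: c for c in corrected}, firstpass, CFG
        )
        (model_id,) = supports
        assert supports[model_id] == {r.read_id for r in reads}
        assert not unassigned
        assert moved == 0

    def test_truncated_read_prefers_model_it_spans(self, setup):
        genome, reads, corrected, firstpass = setup
        # 5'-truncated pile builds its own shorter-span model
        trunc = [
            genome_read(f"t{i}", 450, [("match", 50), ("intron", 400), ("match", 500)])
            for i in range(3)
        ]
        ev = evidence_from_pairs([(500, 900)])
        all_corr, _ = correct_splice_sites(reads + trunc, ev)
        groups = group_by_junction_chain(all_corr)
        fps = build_firstpass(groups, genome)
        assert len(fps) == 2  # split start clusters, same chain
        supports, unassigned, _ = assign_to_firstpass(
            reads + trunc, {c.read_id: c for c in all_corr}, fps, CFG
        )
        assert not unassigned
        by_model = {m: sorted(r) for m, r in supports.items() if r}
        # truncated reads land on the model whose stringent check they pass
        assert any(set(v) == {"t0", "t1", "t2"} for v in by_model.values())

    def test_unmatched_read_reported(self, setup):
        _genome, _reads, _corrected, firstpass = setup
        stranger = genome_read("x", 100, [("match", 300), ("intron", 900), ("match", 200)])
        ev = SpliceEvidence(
            [JunctionEvidence("chr1", 400, 1300, "+", "annotation")]
        )
        corr, _ = correct_splice_sites([stranger], ev)
        supports, unassigned, _ = assign_to_firstpass(
            [stranger], {c.read_id: c for c in corr}, firstpass, CFG
        )
        assert unassigned == {"x"}


class TestFinalize:
    def _fp(self, tid, junctions, start, end, reads, chrom="chr1"):
        exons = []
        bounds = [start]
        for d, a in junctions:
            bounds += [d, a]
        bounds.append(end)
        exons = [
            GenomeInterval(chrom, s, e, "+")
            for s, e in zip(bounds[::2], bounds[1::2])
        ]
        model = TranscriptModel(tid, "g", exons, "novel")
        return FirstPassIsoform(model, set(reads), start, end)

    def test_min_support_threshold(self):
        fp3 = self._fp("n3", [(500, 900)], 100, 1400, {"a", "b", "c"})
        fp2 = self._fp("n2", [(500, 950)], 100, 1400, {"d", "e"})
        out = finalize(
            [fp3, fp2],
            {"n3": fp3.supporting_read_ids, "n2": fp2.supporting_read_ids},
            [],
        )
        assert [m.transcript_id for m, _ in out] == ["n3"]

    def test_duplicate_chain_collapses_onto_annotated(self):
        fp = self._fp("novel1", [(500, 900)], 105, 1395, {"a", "b", "c"})
        annotated = TranscriptModel(
            "known",
            "g",
            [GenomeInterval("chr1", 100, 500, "+"), GenomeInterval("chr1", 900, 1400, "+")],
            "annotated",
        )
        out = finalize(
            [fp],
            {"novel1": fp.supporting_read_ids},
            [(annotated, {"x", "y", "z"})],
        )
        assert len(out) == 1
        model, reads = out[0]
        assert model.source == "annotated"
        assert reads == {"a", "b", "c", "x", "y", "z"}

    def test_empty_inputs_give_empty_set(self):
        assert finalize([], {}, []) == []

    def test_truncation_artifact_absorbed_into_parent(self):
        parent = self._fp(
            "full", [(500, 900), (1200, 1600)], 100, 2000, {f"p{i}" for i in range(6)}
        )
        sub = self._fp("sub", [(1200, 1600)], 950, 2010, {"s0", "s1", "s2"})
        out = finalize(
            [parent, sub],
            {
                "full": parent.supporting_read_ids,
                "sub": sub.supporting_read_ids,
            },
            [],
        )
        assert [m.transcript_id for m, _ in out] == ["full"]
        assert out[0][1] >= {"s0", "s1", "s2"}

    def test_genuine_alternative_chain_not_absorbed(self):
        parent = self._fp(
            "full", [(500, 900), (1200, 1600)], 100, 2000, {f"p{i}" for i in range(6)}
        )
        # skips the first intron entirely: not a terminal subchain
        alt = self._fp("alt", [(500, 1600)], 100, 2000, {"a0", "a1", "a2"})
        out = finalize(
            [parent, alt],
            {"full": parent.supporting_read_ids, "alt": alt.supporting_read_ids},
            [],
        )
        assert sorted(m.transcript_id for m, _ in out) == ["alt", "full"]

    def test_mono_exon_fragment_inside_exon_suppressed(self):
        parent = self._fp(
            "full", [(500, 900)], 100, 1400, {f"p{i}" for i in range(6)}
        )
        frag = self._fp("frag", [], 150, 400, {"m0", "m1", "m2"})
        out = finalize(
            [parent, frag],
            {"full": parent.supporting_read_ids, "frag": frag.supporting_read_ids},
            [],
        )
        assert [m.transcript_id for m, _ in out] == ["full"]

    def test_support_conservation(self):
        fps = [
            self._fp("a", [(500, 900)], 100, 1400, {"r1", "r2", "r3"}),
            self._fp("b", [(500, 950)], 100, 1400, {"r4", "r5", "r6"}),
        ]
        out = finalize(
            [fps[0], fps[1]],
            {"a": fps[0].supporting_read_ids, "b": fps[1].supporting_read_ids},
            [],
        )
        total = sum(len(r) for _, r in out)
        assert total <= 6
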