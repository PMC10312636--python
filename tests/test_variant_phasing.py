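"""Haplotype tabulation, phase-set phasing, HST bias testing and output
sequence generation."""

import pytest

from haplotx.io_formats import GenomeInterval, TranscriptModel, VariantRecord
from haplotx.variant_phasing import (
    Haplotype,
    combine_variant_calls,
    compute_coverage,
    emit_hst_outputs,
    gene_haplotype_labels,
    haplotype_sequence,
    hst_bias_test,
    phase_by_phase_set,
    read_allele_at,
    tabulate_haplotypes,
)

from conftest import make_aln


def hap_read(rid, start, length, alts=None, tags=None):
    """Genome-aligned read matching the reference except at ``alts``
    (pos -> base)."""
    alts = dict(sorted((alts or {}).items()))
    segments = []
    pos = start
    for p, base in alts.items():
        if p >= start + length or p < start:
            continue
        if p > pos:
            segments.append(("match", p - pos))
        segments.append(("mismatch", 1, base))
        pos = p + 1
    if start + length > pos:
        segments.append(("match", start + length - pos))
    aln = make_aln(segments, start=start, chrom="chr1", target_kind="genome", read_id=rid)
    if tags:
        aln.tags.update(tags)
    return aln


V1 = VariantRecord("chr1", 150, "A", "G", 30.0)
V2 = VariantRecord("chr1", 250, "C", "T", 30.0)

ISOFORM = TranscriptModel(
    "iso1", "gene1", [GenomeInterval("chr1", 100, 400, "+")], "annotated"
)


class TestCombine:
    def test_duplicate_sites_merged_with_provenance(self):
        a = VariantRecord("chr1", 150, "A", "G", 30.0, caller="longshot")
        b = VariantRecord("chr1", 150, "A", "G", 44.0, caller="pepper")
        coverage = {"chr1": {150: 20}}
        (merged,) = combine_variant_calls([[a], [b]], coverage, min_coverage=10)
        assert merged.caller == "longshot,pepper"
        assert merged.qual == 44.0

    def test_low_coverage_site_dropped(self):
        coverage = {"chr1": {150: 9}}
        assert combine_variant_calls([[V1]], coverage, min_coverage=10) == []

    def test_no_input_is_error(self):
        with pytest.raises(ValueError, match="no variant input"):
            combine_variant_calls([], {}, 10)

    def test_coverage_from_blocks(self):
        reads = [hap_read(f"r{i}", 100, 100) for i in range(5)]
        cov = compute_coverage(reads)
        assert cov["chr1"][150] == 5
        assert cov["chr1"].get(250, 0) == 0


class TestReadAllele:
    def test_classifications(self):
        assert read_allele_at(hap_read("r", 100, 200), V1) == "ref"
        assert read_allele_at(hap_read("r", 100, 200, {150: "G"}), V1) == "alt"
        assert read_allele_at(hap_read("r", 100, 200, {150: "C"}), V1) == "other"
        assert read_allele_at(hap_read("r", 100, 40), V1) == "uncovered"

    def test_deleted_site_uncovered(self):
        aln = make_aln(
            [("match", 45), ("deletion", 10), ("match", 100)],
            start=100,
            chrom="chr1",
            target_kind="genome",
        )
        assert read_allele_at(aln, V1) == "uncovered"


class TestTabulate:
    def test_clean_diploid(self):
        reads = [hap_read(f"a{i}", 100, 300, {150: "G", 250: "T"}) for i in range(10)]
        reads += [hap_read(f"b{i}", 100, 300) for i in range(10)]
        haps = tabulate_haplotypes(ISOFORM, reads, [V1, V2])
        assert len(haps) == 2
        assert {h.support for h in haps} == {10}
        vectors = {h.allele_vector() for h in haps}
        assert vectors == {("G", "T"), ("A", "C")}

    def test_fraction_threshold_inclusive(self):
        major = [hap_read(f"a{i}", 100, 300, {150: "G"}) for i in range(18)]
        minor = [hap_read(f"b{i}", 100, 300, {150: "G", 250: "T"}) for i in range(2)]
        haps = tabulate_haplotypes(
            ISOFORM, major + minor, [V1, V2],
            min_haplotype_support=2, min_haplotype_fraction=0.10,
            absorb_singletons=False,
        )
        assert len(haps) == 2  # 2/20 = 10% exactly: kept
        haps = tabulate_haplotypes(
            ISOFORM, major + minor[:1] + major[:1], [V1, V2],
            min_haplotype_support=1, min_haplotype_fraction=0.10,
            absorb_singletons=False,
        )
        assert len(haps) == 1  # 1/20 = 5%: dropped

    def test_no_variants_passes_through(self):
        reads = [hap_read("r", 100, 300)]
        assert tabulate_haplotypes(ISOFORM, reads, []) == []

    def test_error_vector_absorbed_into_neighbour(self):
        clean = [hap_read(f"a{i}", 100, 300, {150: "G", 250: "T"}) for i in range(10)]
        noisy = [hap_read("x", 100, 300, {150: "G"})]  # one-off from (G,T)
        haps = tabulate_haplotypes(ISOFORM, clean + noisy, [V1, V2])
        assert len(haps) == 1
        assert haps[0].support == 11

    def test_partial_read_supports_unique_consistent_haplotype(self):
        complete = [hap_read(f"a{i}", 100, 300, {150: "G", 250: "T"}) for i in range(5)]
        complete += [hap_read(f"b{i}", 100, 300) for i in range(5)]
        partial = [hap_read("p", 100, 100, {150: "G"})]  # covers V1 only
        haps = tabulate_haplotypes(ISOFORM, complete + partial, [V1, V2])
        support = {h.allele_vector(): h.support for h in haps}
        assert support[("G", "T")] == 6
        assert support[("A", "C")] == 5

    def test_read_order_invariance_and_deterministic_indices(self):
        reads = [hap_read(f"a{i}", 100, 300, {150: "G", 250: "T"}) for i in range(8)]
        reads += [hap_read(f"b{i}", 100, 300) for i in range(5)]
        h1 = tabulate_haplotypes(ISOFORM, reads, [V1, V2])
        h2 = tabulate_haplotypes(ISOFORM, reads[::-1], [V1, V2])
        assert [(h.haplotype_index, h.allele_vector(), h.support) for h in h1] == [
            (h.haplotype_index, h.allele_vector(), h.support) for h in h2
        ]
        assert h1[0].haplotype_index == 1
        assert h1[0].support >= h1[1].support

    def test_support_bounded_by_isoform_reads(self):
        reads = [hap_read(f"a{i}", 100, 300, {150: "G"}) for i in range(7)]
        haps = tabulate_haplotypes(ISOFORM, reads, [V1])
        assert sum(h.support for h in haps) <= len(reads)


class TestPhaseSet:
    def _phased(self):
        v1 = VariantRecord("chr1", 150, "A", "G", 30.0, phase_set="7", genotype="0|1")
        v2 = VariantRecord("chr1", 250, "C", "T", 30.0, phase_set="7", genotype="0|1")
        return [v1, v2]

    def test_reads_partition_by_tag(self):
        variants = self._phased()
        reads = [
            hap_read(f"a{i}", 100, 300, tags={"HP": 1, "PS": 7}) for i in range(14)
        ]
        reads += [
            hap_read(f"b{i}", 100, 300, {150: "G", 250: "T"}, tags={"HP": 2, "PS": 7})
            for i in range(16)
        ]
        haps, untagged, conflicts = phase_by_phase_set(ISOFORM, reads, variants)
        assert sorted(h.support for h in haps) == [14, 16]
        assert untagged == 0
        vectors = {h.haplotype_index: h.allele_vector() for h in haps}
        assert vectors[1] == ("A", "C")
        assert vectors[2] == ("G", "T")

    def test_single_haplotype(self):
        variants = self._phased()
        reads = [hap_read(f"a{i}", 100, 300, tags={"HP": 1, "PS": 7}) for i in range(5)]
        haps, _, _ = phase_by_phase_set(ISOFORM, reads, variants)
        assert len(haps) == 1

    def test_conflicting_read_follows_tag_and_is_counted(self):
        variants = self._phased()
        reads = [hap_read(f"a{i}", 100, 300, tags={"HP": 1, "PS": 7}) for i in range(4)]
        # carries hap2 alleles but is tagged hap1
        reads.append(
            hap_read("turncoat", 100, 300, {150: "G", 250: "T"}, tags={"HP": 1, "PS": 7})
        )
        haps, _, conflicts = phase_by_phase_set(ISOFORM, reads, variants)
        assert len(haps) == 1
        assert haps[0].support == 5
        assert conflicts == 2  # one read, two variant positions

    def test_untagged_reads_counted_and_excluded(self):
        variants = self._phased()
        reads = [hap_read(f"a{i}", 100, 300, tags={"HP": 1, "PS": 7}) for i in range(3)]
        reads.append(hap_read("plain", 100, 300))
        haps, untagged, _ = phase_by_phase_set(ISOFORM, reads, variants)
        assert untagged == 1
        assert sum(h.support for h in haps) == 3


class TestHstBias:
    def test_strong_bias_is_significant(self):
        counts = {
            "g": {
                "isoA": {"hap1": 20, "hap2": 0},
                "isoB": {"hap1": 0, "hap2": 20},
            }
        }
        results = hst_bias_test(counts)
        strong = [r for r in results if r.isoform_id == "isoA" and r.haplotype_label == "hap1"]
        assert strong[0].p == pytest.approx(2 / 137846528820, rel=1e-6)
        assert strong[0].significant

    def test_balanced_counts_not_significant(self):
        counts = {
            "g": {
                "isoA": {"hap1": 10, "hap2": 10},
                "isoB": {"hap1": 10, "hap2": 10},
            }
        }
        results = hst_bias_test(counts)
        assert all(r.p == 1.0 for r in results)
        assert not any(r.significant for r in results)

    def test_single_isoform_gene_skipped(self):
        assert hst_bias_test({"g": {"isoA": {"hap1": 5, "hap2": 5}}}) == []

    def test_gene_labels_cluster_compatible_haplotypes(self):
        h_a1 = Haplotype("isoA", {150: "G", 250: "T"}, 12, 1)
        h_a2 = Haplotype("isoA", {150: "A", 250: "C"}, 10, 2)
        h_b1 = Haplotype("isoB", {250: "T"}, 8, 1)  # compatible with h_a1
        labels = gene_haplotype_labels({"isoA": [h_a1, h_a2], "isoB": [h_b1]})
        assert labels["isoA"] == {"hap1": 12, "hap2": 10}
        assert labels["isoB"] == {"hap1": 8}


class TestEmitOutputs:
    GENOME = {"chr1": "ACGTACGTAC" * 100}

    def test_single_alt_changes_one_base(self):
        hap = Haplotype("iso1", {150: "G"}, 5, 1, [V1])
        ref_seq = haplotype_sequence(
            self.GENOME, ISOFORM, Haplotype("iso1", {}, 5, 2, [])
        )
        alt_seq = haplotype_sequence(self.GENOME, ISOFORM, hap)
        diffs = [i for i, (a, b) in enumerate(zip(ref_seq, alt_seq)) if a != b]
        assert diffs == [50]  # pos 150 − exon start 100

    def test_ref_only_haplotype_is_reference_sequence(self):
        from haplotx.io_formats import transcript_sequence

        hap = Haplotype("iso1", {}, 5, 1, [])
        assert haplotype_sequence(self.GENOME, ISOFORM, hap) == transcript_sequence(
            self.GENOME, ISOFORM
        )

    def test_minus_strand_alt_maps_to_complement_offset(self):
        iso = TranscriptModel(
            "m1",
            "gene2",
            [
                GenomeInterval("chr1", 100, 200, "-"),
                GenomeInterval("chr1", 300, 400, "-"),
            ],
            "annotated",
        )
        # genome-level T→C inside exon 2
        pos = 350
        genome = {"chr1": "T" * 1000}
        var = VariantRecord("chr1", pos, "T", "C", 30.0)
        hap = Haplotype("m1", {pos: "C"}, 5, 1, [var])
        seq = haplotype_sequence(genome, iso, hap)
        # transcript offset: exon2 is first in transcript order (minus strand);
        # offset within exon2 = exon2.end - 1 - pos
        tx_offset = 400 - 1 - pos
        assert seq[tx_offset] == "G"  # complement of C
        assert seq.count("G") == 1
        assert len(seq) == 200

    def test_emit_bundles_names_and_vcf_map(self):
        haps = {
            "iso1": [
                Haplotype("iso1", {150: "G"}, 5, 1, [V1]),
                Haplotype("iso1", {}, 4, 2, [V1]),
            ]
        }
        seqs, models, iso_map = emit_hst_outputs(haps, {"iso1": ISOFORM}, self.GENOME)
        assert set(seqs) == {"iso1_1_gene1", "iso1_2_gene1"}
        assert [m.transcript_id for m in models] == ["iso1_1", "iso1_2"]
        assert iso_map == {("chr1", 150, "G"): ["iso1_1_gene1"]}
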