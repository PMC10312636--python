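"""Integration of sequence variants into isoform models.

Two phasing modes are provided, neither of which ever calls variants
itself — variant calls are consumed from VCFs:

* *ploidy-agnostic tabulation* — for each isoform, the allele vectors its
  supporting reads carry over the variant positions inside its exons are
  counted; frequent vectors become haplotypes.  Nothing caps the number of
  haplotypes at two, which matters for aneuploid tumours and for RNA edits
  masquerading as variants;
* *phase-set mode* — reads carry haplotype (HP) and phase-set (PS) tags
  from a diploid phasing caller; reads of an isoform are partitioned by
  (PS, HP) and allele vectors are taken from the phased genotypes in the
  VCF, yielding at most two haplotypes per phase set.

Haplotype-specific transcript (HST) bias is then tested per gene: for each
(isoform, haplotype) pair a 2×2 table of reads (this isoform vs the gene's
other isoforms × this haplotype vs the others) goes through Fisher's exact
test with Benjamini–Hochberg adjustment across all tests.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import (
    ReadAlignment,
    TranscriptModel,
    VariantRecord,
    read_vcf,
    reverse_complement,
    transcript_sequence,
)
from .stats_core import ContingencyTable2x2, bh_adjust, fisher_exact_two_sided

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Variant combination
# ---------------------------------------------------------------------------


def compute_coverage(reads: Iterable[ReadAlignment]) -> dict[str, Counter]:
    """Per-chromosome exonic read depth from alignment blocks."""
    depth: dict[str, Counter] = defaultdict(Counter)
    for read in reads:
        for block in read.blocks:
            for pos in range(block.start, block.end):
                depth[block.chrom][pos] += 1
    return dict(depth)


def combine_variant_calls(
    vcf_records: Sequence[Sequence[VariantRecord]],
    coverage: Mapping[str, Counter],
    min_coverage: int = 10,
) -> list[VariantRecord]:
    """Union SNV calls from several callers, filtered by read coverage.

    Sites with exonic depth < ``min_coverage`` are dropped.  Duplicates
    (same chrom/pos0/alt) merge keeping the maximum quality; caller
    provenance is concatenated.
    """
    if not vcf_records:
        raise ValueError("no variant input")
    merged: dict[tuple[str, int, str], VariantRecord] = {}
    for records in vcf_records:
        for rec in records:
            if coverage.get(rec.chrom, Counter()).get(rec.pos0, 0) < min_coverage:
                continue
            key = rec.key()
            if key in merged:
                prev = merged[key]
                callers = sorted(set(prev.caller.split(",")) | set(rec.caller.split(",")))
                best = prev if prev.qual >= rec.qual else rec
                merged[key] = VariantRecord(
                    chrom=best.chrom,
                    pos0=best.pos0,
                    ref_allele=best.ref_allele,
                    alt_allele=best.alt_allele,
                    qual=max(prev.qual, rec.qual),
                    phase_set=prev.phase_set or rec.phase_set,
                    genotype=prev.genotype or rec.genotype,
                    caller=",".join(callers),
                )
            else:
                merged[key] = rec
    return [merged[k] for k in sorted(merged)]


def combine_variant_files(
    vcf_paths: Sequence, reads: Sequence[ReadAlignment], min_coverage: int = 10
) -> list[VariantRecord]:
    if not vcf_paths:
        raise ValueError("no variant input")
    coverage = compute_coverage(reads)
    return combine_variant_calls(
        [read_vcf(p) for p in vcf_paths], coverage, min_coverage
    )


# ---------------------------------------------------------------------------
# Per-read allele classification
# ---------------------------------------------------------------------------


def read_allele_at(read: ReadAlignment, variant: VariantRecord) -> str:
    """Classify the base a genome-aligned read carries at a variant site.

    Returns "ref", "alt", "other", or "uncovered" (position deleted,
    spliced out, or outside the alignment span).
    """
    state = read.op_state_at(variant.pos0)
    if state in ("deletion", "intron", "uncovered"):
        return "uncovered"
    if state == "match":
        return "ref"
    base = read.base_at(variant.pos0)
    if base == variant.alt_allele:
        return "alt"
    return "other"


# ---------------------------------------------------------------------------
# Ploidy-agnostic tabulation
# ---------------------------------------------------------------------------


@dataclass
class Haplotype:
    """A co-occurring combination of variant alleles on one isoform."""

    isoform_id: str
    alleles: dict[int, str]  # variant pos0 -> allele base carried
    support: int
    haplotype_index: int
    variants: list[VariantRecord] = field(default_factory=list)

    def allele_vector(self) -> tuple[str, ...]:
        return tuple(self.alleles[p] for p in sorted(self.alleles))


def _variants_in_exons(
    isoform: TranscriptModel, variants: Sequence[VariantRecord]
) -> list[VariantRecord]:
    out = []
    for v in variants:
        if v.chrom != isoform.chrom:
            continue
        if any(e.contains_point(v.pos0) for e in isoform.exons):
            out.append(v)
    return sorted(out, key=lambda v: v.pos0)


def tabulate_haplotypes(
    isoform: TranscriptModel,
    supporting_reads: Sequence[ReadAlignment],
    variants: Sequence[VariantRecord],
    min_haplotype_support: int = 3,
    min_haplotype_fraction: float = 0.10,
    absorb_singletons: bool = True,
) -> list[Haplotype]:
    """Count the variant-allele combinations carried by an isoform's reads.

    Each read maps to a vector of ref/alt calls over the variant positions
    inside the isoform's exons.  Complete vectors are counted directly.
    Low-support vectors differing from a surviving vector at exactly one
    position are absorbed into it (sequencing-error dilution).  Vectors
    with support ≥ ``min_haplotype_support`` and ≥ ``min_haplotype_fraction``
    of the isoform's reads become haplotypes, indexed by descending
    support.  Reads not covering every position add support to the unique
    surviving haplotype consistent with their covered positions, when one
    exists.  An isoform overlapping no variants yields an empty list.
    """
    sites = _variants_in_exons(isoform, variants)
    if not sites:
        return []
    positions = [v.pos0 for v in sites]
    by_pos = {v.pos0: v for v in sites}
    n_reads = len(supporting_reads)

    complete: Counter = Counter()
    partial: list[dict[int, str]] = []
    for read in supporting_reads:
        calls: dict[int, str] = {}
        for v in sites:
            allele = read_allele_at(read, v)
            if allele in ("ref", "alt"):
                calls[v.pos0] = v.ref_allele if allele == "ref" else v.alt_allele
        if len(calls) == len(positions):
            complete[tuple(calls[p] for p in positions)] += 1
        elif calls:
            partial.append(calls)

    counts = dict(complete)
    if absorb_singletons and counts:
        survivors = {
            vec for vec, n in counts.items() if n >= min_haplotype_support
        }
        for vec in sorted(counts, key=lambda v: (counts[v], v)):
            if vec in survivors or counts[vec] >= min_haplotype_support:
                continue
            neighbours = [
                s
                for s in survivors
                if sum(a != b for a, b in zip(vec, s)) == 1
            ]
            if neighbours:
                target = max(neighbours, key=lambda s: (counts[s], s))
                counts[target] += counts.pop(vec)

    kept = [
        (vec, n)
        for vec, n in counts.items()
        if n >= min_haplotype_support and n >= min_haplotype_fraction * n_reads
    ]

    # partial reads support the unique consistent surviving vector
    extra: Counter = Counter()
    for calls in partial:
        consistent = [
            vec
            for vec, _n in kept
            if all(vec[positions.index(p)] == b for p, b in calls.items())
        ]
        if len(consistent) == 1:
            extra[consistent[0]] += 1

    haplotypes = []
    ordered = sorted(kept, key=lambda t: (-(t[1] + extra[t[0]]), t[0]))
    for idx, (vec, n) in enumerate(ordered, start=1):
        alleles = dict(zip(positions, vec))
        haplotypes.append(
            Haplotype(
                isoform_id=isoform.transcript_id,
                alleles=alleles,
                support=n + extra[vec],
                haplotype_index=idx,
                variants=[by_pos[p] for p in positions],
            )
        )
    return haplotypes


# ---------------------------------------------------------------------------
# Phase-set (diploid) mode
# ---------------------------------------------------------------------------


def phase_by_phase_set(
    isoform: TranscriptModel,
    supporting_reads: Sequence[ReadAlignment],
    variants: Sequence[VariantRecord],
    min_haplotype_support: int = 3,
) -> tuple[list[Haplotype], int, int]:
    """Partition an isoform's reads by their (PS, HP) tags.

    Allele vectors come from the VCF's phased genotypes: haplotype h of
    phase set ps carries allele GT[h-1] of each phased variant in ps.  A
    read whose carried base conflicts with its tag still follows the tag;
    conflicts are counted.  Returns (haplotypes, n untagged reads,
    n allele conflicts).
    """
    sites = _variants_in_exons(isoform, variants)
    if not sites:
        return [], 0, 0
    phased = [v for v in sites if v.phase_set is not None and v.genotype and "|" in v.genotype]
    partitions: dict[tuple[str, int], list[ReadAlignment]] = defaultdict(list)
    untagged = 0
    for read in supporting_reads:
        hp = read.tags.get("HP")
        ps = read.tags.get("PS")
        if hp is None:
            untagged += 1
            continue
        partitions[(str(ps), int(hp))].append(read)

    conflicts = 0
    haplotypes: list[Haplotype] = []
    for (ps, hp) in sorted(partitions):
        reads = partitions[(ps, hp)]
        if len(reads) < min_haplotype_support:
            continue
        alleles: dict[int, str] = {}
        used: list[VariantRecord] = []
        for v in phased:
            if v.phase_set != ps:
                continue
            gt = v.genotype.split("|")
            if hp - 1 >= len(gt) or gt[hp - 1] == ".":
                continue
            allele = v.ref_allele if gt[hp - 1] == "0" else v.alt_allele
            alleles[v.pos0] = allele
            used.append(v)
            for read in reads:
                call = read_allele_at(read, v)
                carried = (
                    v.ref_allele
                    if call == "ref"
                    else v.alt_allele
                    if call == "alt"
                    else None
                )
                if carried is not None and carried != allele:
                    conflicts += 1
        if not alleles:
            continue
        haplotypes.append(
            Haplotype(
                isoform_id=isoform.transcript_id,
                alleles=alleles,
                support=len(reads),
                haplotype_index=hp,
                variants=used,
            )
        )
    return haplotypes, untagged, conflicts


# ---------------------------------------------------------------------------
# HST bias test
# ---------------------------------------------------------------------------


@dataclass
class HstTestResult:
    gene_id: str
    isoform_id: str
    haplotype_label: str
    table: ContingencyTable2x2
    p: float
    p_adj: float = 1.0

    @property
    def significant(self) -> bool:
        return self.p_adj < 0.05


def hst_bias_test(
    gene_counts: Mapping[str, Mapping[str, Mapping[str, int]]],
    adjust_method: str = "bh",
) -> list[HstTestResult]:
    """Test every (isoform, haplotype) pair for haplotype bias.

    ``gene_counts`` maps gene_id → isoform_id → haplotype label → read
    count.  Genes need ≥2 isoforms and ≥2 haplotype labels; others are
    skipped.  The 2×2 table contrasts this isoform vs the gene's other
    isoforms against this haplotype vs the others; p-values are adjusted
    across all tests (transcriptome-wide).
    """
    results: list[HstTestResult] = []
    for gene_id in sorted(gene_counts):
        isoforms = gene_counts[gene_id]
        labels = sorted({h for counts in isoforms.values() for h in counts})
        if len(isoforms) < 2 or len(labels) < 2:
            logger.debug("gene %s skipped for HST test (too few isoforms/haplotypes)", gene_id)
            continue
        totals = {
            iso: sum(counts.values()) for iso, counts in isoforms.items()
        }
        grand = sum(totals.values())
        label_totals = {
            lab: sum(counts.get(lab, 0) for counts in isoforms.values())
            for lab in labels
        }
        for iso in sorted(isoforms):
            for lab in labels:
                a = isoforms[iso].get(lab, 0)
                b = totals[iso] - a
                c = label_totals[lab] - a
                d = grand - a - b - c
                table = ContingencyTable2x2(a, b, c, d)
                results.append(
                    HstTestResult(
                        gene_id=gene_id,
                        isoform_id=iso,
                        haplotype_label=lab,
                        table=table,
                        p=fisher_exact_two_sided(table),
                    )
                )
    if results:
        adjusted = bh_adjust([r.p for r in results], method=adjust_method)
        for r, padj in zip(results, adjusted):
            r.p_adj = padj
    return results


def gene_haplotype_labels(
    haplotypes_by_isoform: Mapping[str, Sequence[Haplotype]],
) -> dict[str, dict[str, int]]:
    """Cluster per-isoform haplotypes of one gene into gene-level labels.

    Two haplotypes are compatible when they agree at every shared variant
    position and share at least one.  Haplotypes are processed in
    descending support order and greedily joined to the first compatible
    cluster.  Returns isoform_id → {label: support}.
    """
    all_haps: list[tuple[str, Haplotype]] = []
    for iso in sorted(haplotypes_by_isoform):
        for hap in haplotypes_by_isoform[iso]:
            all_haps.append((iso, hap))
    all_haps.sort(key=lambda t: (-t[1].support, t[0], t[1].haplotype_index))

    clusters: list[dict[int, str]] = []
    assignment: dict[tuple[str, int], int] = {}
    for iso, hap in all_haps:
        placed = False
        for ci, proto in enumerate(clusters):
            shared = set(proto) & set(hap.alleles)
            if shared and all(proto[p] == hap.alleles[p] for p in shared):
                proto.update(hap.alleles)
                assignment[(iso, hap.haplotype_index)] = ci
                placed = True
                break
        if not placed:
            clusters.append(dict(hap.alleles))
            assignment[(iso, hap.haplotype_index)] = len(clusters) - 1
    out: dict[str, dict[str, int]] = defaultdict(dict)
    for iso, hap in all_haps:
        label = f"hap{assignment[(iso, hap.haplotype_index)] + 1}"
        out[iso][label] = out[iso].get(label, 0) + hap.support
    return dict(out)


# ---------------------------------------------------------------------------
# HST output generation
# ---------------------------------------------------------------------------


def hst_name(isoform: TranscriptModel, haplotype_index: int) -> str:
    return f"{isoform.transcript_id}_{haplotype_index}_{isoform.gene_id}"


def haplotype_sequence(
    genome, isoform: TranscriptModel, haplotype: Haplotype
) -> str:
    """Spliced isoform sequence with the haplotype's alt alleles substituted.

    Substitution happens in genome orientation before the minus-strand
    reverse complement, so a genome-level T→C alt on a minus-strand isoform
    appears as A→G in the transcript sequence.
    """
    pieces = []
    for exon in isoform.exons:
        seq = list(
            str(genome[exon.chrom][exon.start : exon.end]).upper()
        )
        for pos, allele in haplotype.alleles.items():
            if exon.start <= pos < exon.end:
                seq[pos - exon.start] = allele
        pieces.append("".join(seq))
    seq = "".join(pieces)
    for pos in haplotype.alleles:
        assert any(e.start <= pos < e.end for e in isoform.exons), (
            "allele substitution outside exons"
        )
    return reverse_complement(seq) if isoform.strand == "-" else seq


def emit_hst_outputs(
    haplotypes_by_isoform: Mapping[str, Sequence[Haplotype]],
    isoforms: Mapping[str, TranscriptModel],
    genome,
) -> tuple[dict[str, str], list[TranscriptModel], dict[tuple[str, int, str], list[str]]]:
    """Build the HST deliverables.

    Returns (sequences by HST name, duplicated isoform models named per
    haplotype, and a map (chrom, pos0, alt) → HST names for VCF ISO
    annotation).
    """
    seqs: dict[str, str] = {}
    models: list[TranscriptModel] = []
    iso_map: dict[tuple[str, int, str], list[str]] = defaultdict(list)
    for iso_id in sorted(haplotypes_by_isoform):
        model = isoforms[iso_id]
        for hap in haplotypes_by_isoform[iso_id]:
            name = hst_name(model, hap.haplotype_index)
            seqs[name] = haplotype_sequence(genome, model, hap)
            models.append(
                TranscriptModel(
                    transcript_id=f"{model.transcript_id}_{hap.haplotype_index}",
                    gene_id=model.gene_id,
                    exons=list(model.exons),
                    source=model.source,
                )
            )
            for v in hap.variants:
                if hap.alleles.get(v.pos0) == v.alt_allele:
                    iso_map[v.key()].append(name)
    return seqs, models, dict(iso_map)
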