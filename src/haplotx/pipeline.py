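"""Workflow orchestration: the collapse and editing entry points.

``run_collapse`` ties together annotation-reliant read assignment, novel
isoform collapse and (optionally) variant phasing; ``run_editing`` runs
the strand-aware editing analyses on two pooled condition alignments.
Both write their artifacts plus a ``manifest.json`` with per-stage read
counts, because most intermediate claims one wants to verify about these
pipelines are counts.  Everything is deterministic for a fixed input.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import editing_analysis as ed
from . import isoform_collapse as collapse
from . import variant_phasing as phasing
from .io_formats import (
    ReadAlignment,
    TranscriptModel,
    read_alignments,
    read_fasta,
    read_gtf,
    transcript_sequence,
    write_fasta,
    write_isoforms,
    write_vcf,
)
from .transcript_assignment import (
    FidelityConfig,
    assign_reads,
    select_best_transcript_alignments,
    supported_annotated_isoforms,
)

logger = logging.getLogger(__name__)


def _load_genome(genome):
    return read_fasta(genome) if isinstance(genome, (str, Path)) else genome


def _load_annotation(annotation):
    if isinstance(annotation, (str, Path)):
        return read_gtf(annotation)
    return annotation


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_collapse(
    genome,
    annotation,
    genome_sam,
    transcriptome_sam=None,
    out_dir="collapse_out",
    vcf_paths: Sequence = (),
    phase_mode: str = "tabulate",
    junction_bed=None,
    fidelity: FidelityConfig | None = None,
    correction_window: int = 10,
    end_window: int = 100,
    min_coverage: int = 10,
    min_haplotype_support: int = 3,
    min_haplotype_fraction: float = 0.10,
    filter_subchains: bool = True,
    annotation_reliant: bool = True,
) -> dict:
    """Run isoform detection (annotated assignment + novel collapse) and
    optional haplotype phasing; returns the manifest dict.

    ``transcriptome_sam`` may be None, in which case the annotation-reliant
    assignment stage is skipped and every read goes through novel-model
    collapse (useful with an intentionally empty annotation).
    """
    cfg = fidelity or FidelityConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = _load_genome(genome)
    annotation = _load_annotation(annotation)
    models = {
        m.transcript_id: m
        for gene_models in annotation.values()
        for m in gene_models
    }

    genome_alns = [
        a
        for a in read_alignments(genome_sam, "genome", reference=genome)
        if not (a.is_secondary or a.is_supplementary)
    ]
    by_read = {a.read_id: a for a in genome_alns}
    all_read_ids = set(by_read)

    # stage 1: annotation-reliant assignment
    assignments = []
    unassigned = set(all_read_ids)
    annotated_supported: list[tuple[TranscriptModel, set[str]]] = []
    if annotation_reliant and transcriptome_sam is not None and models:
        tx_ref = {
            tid: transcript_sequence(genome, m) for tid, m in models.items()
        }
        tx_alns = [
            a
            for a in read_alignments(
                transcriptome_sam, "transcript", reference=tx_ref
            )
            if not (a.is_secondary or a.is_supplementary)
        ]
        candidates = select_best_transcript_alignments(tx_alns)
        assignments, not_assigned = assign_reads(candidates, models, cfg)
        annotated_supported = supported_annotated_isoforms(
            assignments, models, cfg
        )
        assigned_ids = {a.read_id for a in assignments}
        unassigned = (all_read_ids - assigned_ids) | (
            not_assigned & all_read_ids
        )

    # stage 2: novel collapse on unassigned reads
    unassigned_alns = [by_read[r] for r in sorted(unassigned)]
    evidence_list = collapse.evidence_from_annotation(annotation)
    if junction_bed is not None:
        evidence_list += collapse.evidence_from_junction_bed(junction_bed)
    evidence_list += collapse.evidence_from_reads(unassigned_alns)
    evidence = collapse.SpliceEvidence(
        evidence_list, min_long_read_support=cfg.min_support
    )
    corrected, flagged = collapse.correct_splice_sites(
        unassigned_alns, evidence, window=correction_window
    )
    corrected_by_id = {c.read_id: c for c in corrected}
    groups = collapse.group_by_junction_chain(corrected)
    firstpass = collapse.build_firstpass(groups, genome, end_window=end_window)
    supports, fp_unassigned, moved = collapse.assign_to_firstpass(
        [by_read[c.read_id] for c in corrected],
        corrected_by_id,
        firstpass,
        cfg,
    )
    final = collapse.finalize(
        firstpass,
        supports,
        annotated_supported,
        min_support=cfg.min_support,
        filter_subchains=filter_subchains,
        end_window=end_window,
    )

    final_models = [m for m, _ in final]
    write_isoforms(
        final_models,
        out / "isoforms.bed",
        out / "isoforms.gtf",
        out / "isoforms.fa",
        genome,
    )
    read_map = []
    for model, reads in final:
        for rid in sorted(reads):
            read_map.append((rid, model.transcript_id))
    pd.DataFrame(read_map, columns=["read_id", "isoform_id"]).to_csv(
        out / "read_map.tsv", sep="\t", index=False
    )

    manifest = {
        "stage_counts": {
            "input_reads": len(all_read_ids),
            "assigned_annotated": len(assignments),
            "unassigned": len(unassigned),
            "uncorrectable": len(flagged),
            "firstpass_models": len(firstpass),
            "reads_moved_between_groups": moved,
            "final_isoforms": len(final),
            "final_annotated": sum(
                1 for m, _ in final if m.source == "annotated"
            ),
            "final_novel": sum(1 for m, _ in final if m.source == "novel"),
        },
        "config_hash": _config_hash(
            {
                "fidelity": vars(cfg),
                "correction_window": correction_window,
                "end_window": end_window,
                "phase_mode": phase_mode,
            }
        ),
    }

    # stage 3: variant phasing
    if vcf_paths:
        variants = phasing.combine_variant_files(
            vcf_paths, genome_alns, min_coverage=min_coverage
        )
        final_by_id = {m.transcript_id: m for m, _ in final}
        haplotypes_by_iso: dict[str, list[phasing.Haplotype]] = {}
        n_untagged = n_conflicts = 0
        for model, read_ids in final:
            reads = [by_read[r] for r in sorted(read_ids) if r in by_read]
            if phase_mode == "phaseset":
                haps, untagged, conflicts = phasing.phase_by_phase_set(
                    model, reads, variants, min_haplotype_support
                )
                n_untagged += untagged
                n_conflicts += conflicts
            else:
                haps = phasing.tabulate_haplotypes(
                    model,
                    reads,
                    variants,
                    min_haplotype_support,
                    min_haplotype_fraction,
                )
            if haps:
                haplotypes_by_iso[model.transcript_id] = haps
        gene_groups: dict[str, dict[str, Sequence[phasing.Haplotype]]] = (
            defaultdict(dict)
        )
        for iso_id, haps in haplotypes_by_iso.items():
            gene_groups[final_by_id[iso_id].gene_id][iso_id] = haps
        hst_counts: dict[str, dict[str, dict[str, int]]] = {}
        for gene_id, iso_haps in gene_groups.items():
            hst_counts[gene_id] = phasing.gene_haplotype_labels(iso_haps)
        hst_results = phasing.hst_bias_test(hst_counts)

        seqs, hst_models, iso_map = phasing.emit_hst_outputs(
            haplotypes_by_iso, final_by_id, genome
        )
        write_fasta(out / "hst.fa", seqs)
        from .io_formats import write_bed12, write_gtf

        write_bed12(out / "hst.bed", hst_models)
        write_gtf(out / "hst.gtf", hst_models)
        write_vcf(
            out / "hst.vcf",
            variants,
            contigs={c: len(genome[c]) for c in sorted(genome)},
            iso_map=iso_map,
        )
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "isoform_id": r.isoform_id,
                    "haplotype": r.haplotype_label,
                    "a": r.table.a,
                    "b": r.table.b,
                    "c": r.table.c,
                    "d": r.table.d,
                    "p": r.p,
                    "p_adj": r.p_adj,
                    "significant": r.significant,
                }
                for r in hst_results
            ]
        ).to_csv(out / "hst_tests.tsv", sep="\t", index=False)
        manifest["stage_counts"].update(
            {
                "variants_combined": len(variants),
                "isoforms_with_haplotypes": len(haplotypes_by_iso),
                "hst_tests": len(hst_results),
                "hst_significant": sum(1 for r in hst_results if r.significant),
                "untagged_reads": n_untagged,
                "tag_allele_conflicts": n_conflicts,
            }
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    counts = manifest["stage_counts"]
    assert (
        counts["assigned_annotated"] + counts["unassigned"]
        == counts["input_reads"]
    ), "read conservation violated"
    return manifest


def read_known_sites_bed(path) -> set[tuple[str, int]]:
    """Known editing sites from a BED file (chrom, pos0 per line)."""
    sites = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            sites.add((f[0], int(f[1])))
    return sites


def candidate_edit_positions(
    variants, annotation: Mapping[str, Sequence[TranscriptModel]]
) -> tuple[list[tuple[str, int]], dict[tuple[str, int], str]]:
    """Candidate inosine positions from variant calls.

    Keeps A→G records in plus-strand genes and T→C records in minus-strand
    genes; returns positions plus their resolved gene strands.
    """
    positions = []
    strand_map = {}
    for v in variants:
        strand = _strand_at(annotation, v.chrom, v.pos0)
        if strand is None:
            continue
        if (strand == "+" and v.ref_allele == "A" and v.alt_allele == "G") or (
            strand == "-" and v.ref_allele == "T" and v.alt_allele == "C"
        ):
            positions.append((v.chrom, v.pos0))
            strand_map[(v.chrom, v.pos0)] = strand
    return positions, strand_map


def _strand_at(annotation, chrom: str, pos0: int) -> str | None:
    found = set()
    for gene_models in annotation.values():
        for m in gene_models:
            if m.chrom == chrom and m.start <= pos0 < m.end:
                found.add(m.strand)
    if len(found) == 1:
        return found.pop()
    return None


def run_editing(
    genome,
    annotation,
    condition_sams: Mapping[str, object],
    control: str,
    knockdown: str | None = None,
    out_dir="editing_out",
    vcf_paths: Sequence = (),
    known_sites_bed=None,
    min_coverage: int = 10,
    min_delta: float = 0.10,
    alpha: float = 0.05,
    type1_threshold: float = 0.40,
    type2_window: int = 150,
    type2_min_edits: int = 3,
    k_nearest: int = 20,
    min_pair_distance: int = 50,
) -> dict:
    """Run the long-read editing analyses; returns the manifest dict.

    With a single condition the differential stage is skipped with a
    warning; hyperediting and coordination analyses still run on the
    control condition.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = _load_genome(genome)
    annotation = _load_annotation(annotation)

    condition_reads = {
        cond: [
            a
            for a in read_alignments(path, "genome", reference=genome)
            if not (a.is_secondary or a.is_supplementary)
        ]
        for cond, path in sorted(condition_sams.items())
    }

    strand_map: dict[tuple[str, int], str] = {}
    positions: list[tuple[str, int]] = []
    if vcf_paths:
        variants = phasing.combine_variant_files(
            vcf_paths,
            [r for reads in condition_reads.values() for r in reads],
            min_coverage=0,
        )
        positions, strand_map = candidate_edit_positions(variants, annotation)
    known = set()
    if known_sites_bed is not None:
        known = read_known_sites_bed(known_sites_bed)
        for chrom, pos in known:
            if (chrom, pos) not in strand_map:
                strand = _strand_at(annotation, chrom, pos)
                if strand is not None:
                    strand_map[(chrom, pos)] = strand
                    positions.append((chrom, pos))

    sites = ed.pileup_edit_counts(
        condition_reads, positions, strand_map, known_sites=known
    )

    manifest_counts = {
        "conditions": len(condition_reads),
        "candidate_positions": len(positions),
        "piled_sites": len(sites),
    }

    diff_results = []
    if knockdown is not None and knockdown in condition_reads:
        diff_results = ed.differential_editing(
            sites,
            control,
            knockdown,
            min_cov=min_coverage,
            min_delta=min_delta,
            alpha=alpha,
            type1_threshold=type1_threshold,
        )
    else:
        logger.warning("single condition input: differential stage skipped")
    pd.DataFrame(
        [
            {
                "chrom": r.site.chrom,
                "pos0": r.site.pos0,
                "strand": r.site.gene_strand,
                "fraction_control": r.fraction_control,
                "fraction_knockdown": r.fraction_knockdown,
                "delta": r.delta,
                "p": r.p,
                "p_adj": r.p_adj,
                "direction": r.direction,
                "type1_in_control": r.type1_in_control,
                "known": r.site.known,
            }
            for r in diff_results
        ]
    ).to_csv(out / "differential_sites.tsv", sep="\t", index=False)

    control_reads = condition_reads[control]
    edited_sites = [
        s
        for s in sites
        if s.coverage(control) > 0 and s.edit_fraction(control) > 0
    ]
    by_chrom_strand: dict[tuple[str, str], list[int]] = defaultdict(list)
    for s in edited_sites:
        by_chrom_strand[(s.chrom, s.gene_strand)].append(s.pos0)
    regions = []
    for (chrom, strand), pos_list in sorted(by_chrom_strand.items()):
        for region in ed.detect_type2_regions(
            pos_list, chrom, window=type2_window, min_edits=type2_min_edits
        ):
            regions.append((region, strand))
    with open(out / "hyperedited_regions.bed", "w") as fh:
        for region, strand in regions:
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t"
                f"type2_{region.n_edits}edits\t{region.n_edits}\t{strand}\n"
            )

    frac_edited, frac_multi, n_overlap = ed.summarize_read_editing(
        control_reads, sites
    )
    pairs = ed.edit_edit_coordination(
        sites,
        control_reads,
        k_nearest=k_nearest,
        min_distance=min_pair_distance,
        alpha=alpha,
    )
    pd.DataFrame(
        [
            {
                "chrom": r.site_a.chrom,
                "pos_a": r.site_a.pos0,
                "pos_b": r.site_b.pos0,
                "distance": r.distance,
                "both": r.table.a,
                "only_a": r.table.b,
                "only_b": r.table.c,
                "neither": r.table.d,
                "p": r.p,
                "p_adj": r.p_adj,
            }
            for r in pairs
        ]
    ).to_csv(out / "coordinated_pairs.tsv", sep="\t", index=False)

    intron_sites = ed.edit_intron_coordination(
        sites,
        control_reads,
        type1_threshold=type1_threshold,
    )
    pd.DataFrame(
        [
            {
                "chrom": r.site.chrom,
                "pos0": r.site.pos0,
                "strand": r.site.gene_strand,
                "edited": r.n_edited,
                "ref": r.n_ref,
                "spliced_out": r.n_spliced,
                "edit_fraction": r.edit_fraction,
            }
            for r in intron_sites
        ]
    ).to_csv(out / "edit_intron_sites.tsv", sep="\t", index=False)

    manifest_counts.update(
        {
            "differential_sites": len(diff_results),
            "differential_down": sum(
                1 for r in diff_results if r.direction == "down"
            ),
            "type1_in_control": sum(
                1 for r in diff_results if r.type1_in_control
            ),
            "hyperedited_regions": len(regions),
            "reads_overlapping_sites": n_overlap,
            "fraction_reads_edited": round(frac_edited, 6),
            "fraction_edited_reads_multi": round(frac_multi, 6),
            "coordinated_pairs": len(pairs),
            "edit_intron_sites": len(intron_sites),
        }
    )
    manifest = {"stage_counts": manifest_counts}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
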