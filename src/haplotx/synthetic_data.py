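"""Deterministic, seeded generator of synthetic long-read RNA-seq data.

Everything the pipeline consumes can be generated here with no downloads:
a random genome with multi-isoform gene loci (canonical GT–AG introns on
both strands), diploid variant haplotypes, condition-dependent edit sites,
R2C2-like consensus reads (~1% substitution error, 5'/3' truncation), and
truth-derived genome/transcriptome SAM alignments.

The truth-derived SAM path writes alignments directly from simulation
truth, so tests need no external aligner; this deliberately does not
model alignment artifacts (soft-clip wobble, multi-mapping), which is a
documented fidelity limitation.  Reads are emitted with =/X CIGAR ops so
mismatch positions are exact.

All randomness flows from ``SimConfig.seed`` through one
``numpy.random.Generator``; identical configs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pysam

from .io_formats import (
    GenomeInterval,
    TranscriptModel,
    VariantRecord,
    reverse_complement,
    transcript_sequence,
    write_fasta,
    write_gtf,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults emulate R2C2-style consensus data: ~99% per-base accuracy
    (substitution-dominated), moderate 5' truncation from incomplete
    reverse transcription and mild 3' raggedness, and a handful of
    multi-isoform loci per run.  ``variant_density_per_kb`` controls the
    diploid heterozygous SNV rate over exonic sequence.
    """

    seed: int = 0
    n_genes: int = 5
    transcripts_per_gene: int = 2
    n_exons_range: tuple[int, int] = (4, 6)
    exon_len_range: tuple[int, int] = (100, 300)
    intron_len_range: tuple[int, int] = (200, 500)
    error_rate: float = 0.01
    indel_error_rate: float = 0.0
    truncation_prob: float = 0.30
    truncation_5p_mean: float = 50.0
    truncation_3p_mean: float = 20.0
    max_truncation_fraction: float = 0.30
    min_read_length: int = 50
    reads_per_transcript: int = 100
    variant_density_per_kb: float = 1.0
    intergenic_gap: int = 500
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        for p in (self.error_rate, self.indel_error_rate, self.truncation_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class Reference:
    genome: dict[str, str]
    annotation: dict[str, list[TranscriptModel]]  # gene_id -> models

    def models_by_id(self) -> dict[str, TranscriptModel]:
        return {
            m.transcript_id: m
            for models in self.annotation.values()
            for m in models
        }

    def gene_strand_at(self, chrom: str, pos0: int) -> str | None:
        for models in self.annotation.values():
            for m in models:
                if m.chrom == chrom and m.start <= pos0 < m.end:
                    return m.strand
        return None


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_reference(cfg: SimConfig) -> Reference:
    """Generate a genome FASTA-equivalent plus a multi-isoform annotation.

    Gene loci alternate strands along one chromosome.  Each gene's first
    isoform uses the full exon scaffold; subsequent isoforms each skip one
    distinct internal exon, so isoforms of a gene always differ in at
    least one junction.  Intron boundaries carry canonical splice
    dinucleotides (GT..AG, strand-appropriate) so strand can be inferred
    from sequence.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom = cfg.chrom_name
    seq_parts: list[str] = []
    cursor = 0
    annotation: dict[str, list[TranscriptModel]] = {}
    for g in range(cfg.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"gene{g + 1}"
        n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
        # need enough internal exons for the requested skip isoforms
        n_exons = max(n_exons, cfg.transcripts_per_gene + 1)
        exon_lens = rng.integers(
            cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            cfg.intron_len_range[0], cfg.intron_len_range[1] + 1, size=n_exons - 1
        )
        gap = _random_seq(rng, cfg.intergenic_gap)
        seq_parts.append(gap)
        cursor += len(gap)
        exons: list[GenomeInterval] = []
        gene_seq: list[str] = []
        for i, exon_len in enumerate(exon_lens):
            exons.append(
                GenomeInterval(chrom, cursor, cursor + int(exon_len), strand)
            )
            gene_seq.append(_random_seq(rng, int(exon_len)))
            cursor += int(exon_len)
            if i < n_exons - 1:
                intron = list(_random_seq(rng, int(intron_lens[i])))
                if strand == "+":
                    intron[0:2] = "GT"
                    intron[-2:] = "AG"
                else:
                    intron[0:2] = "CT"
                    intron[-2:] = "AC"
                gene_seq.append("".join(intron))
                cursor += int(intron_lens[i])
        seq_parts.append("".join(gene_seq))
        models = [
            TranscriptModel(f"{gene_id}.t1", gene_id, list(exons), "annotated")
        ]
        internal = list(range(1, n_exons - 1))
        for t in range(1, cfg.transcripts_per_gene):
            skip = internal[(t - 1) % len(internal)]
            kept = [e for i, e in enumerate(exons) if i != skip]
            models.append(
                TranscriptModel(f"{gene_id}.t{t + 1}", gene_id, kept, "annotated")
            )
        annotation[gene_id] = models
    seq_parts.append(_random_seq(rng, cfg.intergenic_gap))
    return Reference(genome={chrom: "".join(seq_parts)}, annotation=annotation)


# ---------------------------------------------------------------------------
# Variants and edit sites
# ---------------------------------------------------------------------------


def simulate_diploid_variants(
    cfg: SimConfig, ref: Reference, min_per_gene: int = 1
) -> list[VariantRecord]:
    """Plant phased heterozygous SNVs over each gene's exonic sequence.

    Haplotype 1 carries the reference allele everywhere, haplotype 2 the
    alternate (parental-strain style), with genotype "0|1" and one phase
    set per gene.  Positions avoid splice-flank bases so fidelity checks
    are unaffected.
    """
    rng = np.random.default_rng(cfg.seed + 104729)
    variants: list[VariantRecord] = []
    for g_index, gene_id in enumerate(sorted(ref.annotation)):
        full = ref.annotation[gene_id][0]
        eligible: list[int] = []
        for exon in full.exons:
            lo, hi = exon.start + 10, exon.end - 10
            if hi > lo:
                eligible.extend(range(lo, hi))
        exonic_kb = sum(len(e) for e in full.exons) / 1000.0
        n = max(min_per_gene, int(round(cfg.variant_density_per_kb * exonic_kb)))
        n = min(n, len(eligible))
        positions = sorted(
            int(p) for p in rng.choice(len(eligible), size=n, replace=False)
        )
        for idx in positions:
            pos = eligible[idx]
            ref_base = ref.genome[full.chrom][pos]
            alt_base = str(
                rng.choice([b for b in "ACGT" if b != ref_base])
            )
            variants.append(
                VariantRecord(
                    chrom=full.chrom,
                    pos0=pos,
                    ref_allele=ref_base,
                    alt_allele=alt_base,
                    qual=50.0,
                    phase_set=str(g_index + 1),
                    genotype="0|1",
                    caller="simulated",
                )
            )
    variants.sort(key=lambda v: (v.chrom, v.pos0))
    return variants


@dataclass(frozen=True)
class EditSpec:
    """One planted candidate edit position with per-condition fractions."""

    chrom: str
    pos0: int
    gene_id: str
    strand: str
    fractions: Mapping[str, float]


def place_edit_sites(
    ref: Reference,
    specs: Sequence[Mapping[str, float]],
    seed: int,
    min_spacing: int = 20,
    known_fraction: float = 0.0,
) -> list[EditSpec]:
    """Place candidate edit sites at strand-appropriate bases.

    ``specs`` is one per-condition fraction mapping per requested site;
    positions are drawn from exonic bases that are A on plus-strand genes
    (T on minus-strand genes), at least ``min_spacing`` apart, spread
    round-robin across genes.
    """
    rng = np.random.default_rng(seed)
    per_gene: dict[str, list[int]] = {}
    for gene_id in sorted(ref.annotation):
        full = ref.annotation[gene_id][0]
        want = "A" if full.strand == "+" else "T"
        eligible = [
            p
            for exon in full.exons
            for p in range(exon.start + 10, exon.end - 10)
            if ref.genome[full.chrom][p] == want
        ]
        rng.shuffle(eligible)
        per_gene[gene_id] = eligible
    gene_ids = sorted(ref.annotation)
    used: dict[str, list[int]] = defaultdict(list)
    out: list[EditSpec] = []
    gi = 0
    for fractions in specs:
        placed = False
        for _attempt in range(len(gene_ids)):
            gene_id = gene_ids[gi % len(gene_ids)]
            gi += 1
            full = ref.annotation[gene_id][0]
            pool = per_gene[gene_id]
            while pool:
                pos = pool.pop()
                if all(abs(pos - q) >= min_spacing for q in used[gene_id]):
                    used[gene_id].append(pos)
                    out.append(
                        EditSpec(
                            full.chrom, pos, gene_id, full.strand, dict(fractions)
                        )
                    )
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise ValueError("not enough eligible positions for edit sites")
    out.sort(key=lambda e: (e.chrom, e.pos0))
    return out


def place_edit_cluster(
    ref: Reference,
    gene_id: str,
    n_sites: int,
    span: int,
    fractions: Mapping[str, float],
    seed: int,
) -> list[EditSpec]:
    """Place a hyperediting-style cluster: ``n_sites`` edits within
    ``span`` bp inside one exon of ``gene_id``."""
    rng = np.random.default_rng(seed)
    full = ref.annotation[gene_id][0]
    want = "A" if full.strand == "+" else "T"
    for exon in sorted(full.exons, key=len, reverse=True):
        lo, hi = exon.start + 5, exon.end - 5
        for start in range(lo, max(lo + 1, hi - span)):
            window = [
                p
                for p in range(start, min(start + span, hi))
                if ref.genome[full.chrom][p] == want
            ]
            if len(window) >= n_sites:
                chosen = sorted(
                    int(window[i])
                    for i in rng.choice(len(window), size=n_sites, replace=False)
                )
                return [
                    EditSpec(full.chrom, p, gene_id, full.strand, dict(fractions))
                    for p in chosen
                ]
    raise ValueError("no exon can hold the requested cluster")


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    """One simulated read plus its generation truth."""

    read_id: str
    transcript_id: str
    gene_id: str
    condition: str
    haplotype: int  # 0 = no haplotype assigned
    phase_set: str | None
    tx_start: int  # retained transcript segment, 5'->3'
    tx_end: int
    seq: str  # transcript orientation
    edited_positions: tuple[int, ...]  # genomic
    error_positions: tuple[int, ...]  # transcript offsets
    truncated: bool


def _tx_to_genome_map(model: TranscriptModel) -> list[int]:
    """tx offset (5'->3') -> genomic position."""
    gmap = [p for e in model.exons for p in range(e.start, e.end)]
    return gmap[::-1] if model.strand == "-" else gmap


def simulate_reads(
    cfg: SimConfig,
    ref: Reference,
    variants: Sequence[VariantRecord] = (),
    edit_specs: Sequence[EditSpec] = (),
    condition: str = "sample",
    seed_offset: int = 0,
) -> list[SimRead]:
    """Draw reads from every annotated transcript.

    Each read optionally takes one of two variant haplotypes (when
    ``variants`` are supplied: haplotype 2 carries every alt allele of its
    gene), receives per-site Bernoulli edits at the condition's fraction,
    is truncated at the 5'/3' ends with probability ``truncation_prob``
    (exponential extents, capped), and finally accumulates uniform
    substitution errors at ``error_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 7919 * (seed_offset + 1))
    variants_by_gene: dict[str, list[VariantRecord]] = defaultdict(list)
    for v in variants:
        for gene_id, models in ref.annotation.items():
            full = models[0]
            if full.chrom == v.chrom and full.start <= v.pos0 < full.end:
                variants_by_gene[gene_id].append(v)
                break
    edits_by_gene: dict[str, list[EditSpec]] = defaultdict(list)
    for e in edit_specs:
        edits_by_gene[e.gene_id].append(e)

    reads: list[SimRead] = []
    for gene_id in sorted(ref.annotation):
        gene_variants = variants_by_gene.get(gene_id, [])
        gene_edits = edits_by_gene.get(gene_id, [])
        phase_set = gene_variants[0].phase_set if gene_variants else None
        for model in ref.annotation[gene_id]:
            tx_ref = transcript_sequence(ref.genome, model)
            gmap = _tx_to_genome_map(model)
            g_to_tx = {g: i for i, g in enumerate(gmap)}
            length = len(tx_ref)
            for r in range(cfg.reads_per_transcript):
                hap = int(rng.integers(1, 3)) if gene_variants else 0
                seq = list(tx_ref)
                if hap == 2:
                    for v in gene_variants:
                        tx_pos = g_to_tx.get(v.pos0)
                        if tx_pos is None:
                            continue
                        base = (
                            v.alt_allele
                            if model.strand == "+"
                            else reverse_complement(v.alt_allele)
                        )
                        seq[tx_pos] = base
                edited: list[int] = []
                for e in gene_edits:
                    tx_pos = g_to_tx.get(e.pos0)
                    if tx_pos is None:
                        continue
                    if rng.random() < e.fractions.get(condition, 0.0):
                        # inosine reads as G: G in transcript orientation
                        seq[tx_pos] = "G"
                        edited.append(e.pos0)
                tx_start, tx_end, truncated = 0, length, False
                if rng.random() < cfg.truncation_prob:
                    cap = int(cfg.max_truncation_fraction * length)
                    cut5 = min(int(rng.exponential(cfg.truncation_5p_mean)), cap)
                    cut3 = min(int(rng.exponential(cfg.truncation_3p_mean)), cap)
                    if length - cut5 - cut3 >= cfg.min_read_length:
                        tx_start, tx_end, truncated = cut5, length - cut3, True
                errors: list[int] = []
                n_err = rng.binomial(tx_end - tx_start, cfg.error_rate)
                if n_err:
                    err_pos = rng.choice(
                        tx_end - tx_start, size=n_err, replace=False
                    )
                    for off in sorted(int(x) for x in err_pos):
                        tx_pos = tx_start + off
                        old = seq[tx_pos]
                        choices = [b for b in "ACGT" if b != old]
                        seq[tx_pos] = choices[int(rng.integers(0, 3))]
                        errors.append(tx_pos)
                # an error on an edited base overwrites the G: no longer an edit
                error_set = set(errors)
                edited = sorted(
                    g
                    for g in edited
                    if tx_start <= g_to_tx[g] < tx_end
                    and g_to_tx[g] not in error_set
                )
                reads.append(
                    SimRead(
                        read_id=f"{model.transcript_id}.{condition}.{r}",
                        transcript_id=model.transcript_id,
                        gene_id=gene_id,
                        condition=condition,
                        haplotype=hap,
                        phase_set=phase_set,
                        tx_start=tx_start,
                        tx_end=tx_end,
                        seq="".join(seq[tx_start:tx_end]),
                        edited_positions=tuple(edited),
                        error_positions=tuple(errors),
                        truncated=truncated,
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# Alignment emission
# ---------------------------------------------------------------------------


def _diff_cigar(query: str, target: str) -> list[tuple[int, int]]:
    """=/X CIGAR runs for two equal-length ungapped sequences."""
    ops: list[tuple[int, int]] = []
    for q, t in zip(query, target):
        code = 7 if q == t else 8
        if ops and ops[-1][0] == code:
            ops[-1] = (code, ops[-1][1] + 1)
        else:
            ops.append((code, 1))
    return ops


def write_alignments(
    reads: Sequence[SimRead],
    ref: Reference,
    genome_sam_path,
    transcriptome_sam_path,
    tag_haplotypes: bool = True,
) -> None:
    """Write truth-derived genome and transcriptome SAM files.

    Genome records use =/X/N CIGARs derived from the read's true exon
    blocks (minus-strand reads are stored reverse-complemented with flag
    16, as an aligner would).  Transcriptome records are ungapped =/X
    alignments to the source transcript.  Reads from variant haplotypes
    carry HP and PS tags.
    """
    models = ref.models_by_id()
    genome_header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": chrom, "LN": len(seq)}
                for chrom, seq in sorted(ref.genome.items())
            ],
        }
    )
    tx_ids = sorted(models)
    tx_header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {
                    "SN": tid,
                    "LN": models[tid].length,
                }
                for tid in tx_ids
            ],
        }
    )
    with pysam.AlignmentFile(
        str(genome_sam_path), "wh", header=genome_header
    ) as gout, pysam.AlignmentFile(
        str(transcriptome_sam_path), "wh", header=tx_header
    ) as tout:
        for read in reads:
            model = models[read.transcript_id]
            gmap = _tx_to_genome_map(model)
            positions = gmap[read.tx_start : read.tx_end]
            if model.strand == "-":
                fwd_seq = reverse_complement(read.seq)
                positions = positions[::-1]
            else:
                fwd_seq = read.seq
            # contiguous genomic blocks
            blocks: list[tuple[int, int]] = []
            start = prev = positions[0]
            for p in positions[1:]:
                if p == prev + 1:
                    prev = p
                else:
                    blocks.append((start, prev + 1))
                    start = prev = p
            blocks.append((start, prev + 1))
            cig: list[tuple[int, int]] = []
            offset = 0
            chrom_seq = ref.genome[model.chrom]
            for bi, (bs, be) in enumerate(blocks):
                if bi:
                    cig.append((3, bs - blocks[bi - 1][1]))
                seg = fwd_seq[offset : offset + (be - bs)]
                cig.extend(_diff_cigar(seg, chrom_seq[bs:be]))
                offset += be - bs
            g = pysam.AlignedSegment(genome_header)
            g.query_name = read.read_id
            g.query_sequence = fwd_seq
            g.flag = 16 if model.strand == "-" else 0
            g.reference_id = genome_header.get_tid(model.chrom)
            g.reference_start = blocks[0][0]
            g.mapping_quality = 60
            g.cigartuples = cig
            g.query_qualities = pysam.qualitystring_to_array("I" * len(fwd_seq))
            if tag_haplotypes and read.haplotype:
                g.set_tag("HP", read.haplotype)
                if read.phase_set is not None:
                    g.set_tag("PS", int(read.phase_set))
            gout.write(g)

            tx_ref = transcript_sequence(ref.genome, model)
            t = pysam.AlignedSegment(tx_header)
            t.query_name = read.read_id
            t.query_sequence = read.seq
            t.flag = 0
            t.reference_id = tx_header.get_tid(read.transcript_id)
            t.reference_start = read.tx_start
            t.mapping_quality = 60
            t.cigartuples = _diff_cigar(
                read.seq, tx_ref[read.tx_start : read.tx_end]
            )
            t.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            tout.write(t)


def write_fastq(reads: Sequence[SimRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")


def write_reference(ref: Reference, fasta_path, gtf_path) -> None:
    write_fasta(fasta_path, ref.genome)
    write_gtf(
        gtf_path,
        [m for models in ref.annotation.values() for m in models],
    )


def truth_models(ref: Reference) -> list[TranscriptModel]:
    return [m for models in ref.annotation.values() for m in models]
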