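"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are 0-based half-open internally (BED convention).  GTF
(1-based closed) and VCF (1-based) are converted at the I/O boundary, so no
other module ever sees a 1-based coordinate.

Genome sequences are accepted either as a plain ``Mapping[str, str]`` or as a
:class:`pyfaidx.Fasta`; every function that needs sequence goes through
:func:`fetch_seq` / :func:`chrom_length`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 0-based half-open interval on one strand of one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """An exon chain with strand and gene membership; the unit of isoform
    detection.

    Exons are stored in genomic order (sorted by start) and must be disjoint,
    on one chromosome and one strand.  The junction chain — the ordered list
    of (donor, acceptor) = (exon_i.end, exon_{i+1}.start) pairs — is the key
    used for grouping reads and comparing transcript structures.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomeInterval]
    source: str = "annotated"  # "annotated" | "novel"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons on mixed "
                "chromosomes or strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    def junctions(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    def chain_key(self) -> tuple:
        """Hashable identity of the junction chain (chrom + junctions)."""
        return (self.chrom, self.junctions())

    def exons_in_transcript_order(self) -> list[GenomeInterval]:
        """Exons ordered 5'→3' along the transcript."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def junction_positions_tx(self) -> list[int]:
        """Exon–exon boundary offsets in transcript (5'→3') coordinates."""
        positions, acc = [], 0
        for exon in self.exons_in_transcript_order()[:-1]:
            acc += len(exon)
            positions.append(acc)
        return positions

    def genome_to_tx(self, pos: int) -> int | None:
        """Map a genomic position inside an exon to its transcript offset.

        Returns None for intronic / out-of-range positions.
        """
        acc = 0
        if self.strand == "+":
            for exon in self.exons:
                if exon.contains_point(pos):
                    return acc + (pos - exon.start)
                acc += len(exon)
        else:
            for exon in self.exons[::-1]:
                if exon.contains_point(pos):
                    return acc + (exon.end - 1 - pos)
                acc += len(exon)
        return None


@dataclass(frozen=True)
class AlnOp:
    """One per-base alignment operation against the target.

    kind: match | mismatch | insertion | deletion | intron
    target_pos: 0-based target coordinate where the op starts (for an
        insertion, the target position before which the bases are inserted).
    query_bases: read bases for mismatch/insertion ops (None otherwise).
    """

    kind: str
    length: int
    target_pos: int
    query_bases: str | None = None


@dataclass
class ReadAlignment:
    """Blocks plus per-base edit operations of one read against the genome
    or a transcript; the unit of fidelity checking."""

    read_id: str
    target_id: str
    target_kind: str  # "genome" | "transcript"
    blocks: list[GenomeInterval]
    ops: list[AlnOp]
    mapq: int
    strand: str = "+"
    is_secondary: bool = False
    is_supplementary: bool = False
    tags: dict = field(default_factory=dict)

    @property
    def target_start(self) -> int:
        return self.blocks[0].start

    @property
    def target_end(self) -> int:
        return self.blocks[-1].end

    def matched_bases(self) -> int:
        return sum(o.length for o in self.ops if o.kind == "match")

    def mismatched_bases(self) -> int:
        return sum(o.length for o in self.ops if o.kind == "mismatch")

    def inserted_bases(self) -> int:
        return sum(o.length for o in self.ops if o.kind == "insertion")

    def deleted_bases(self) -> int:
        return sum(o.length for o in self.ops if o.kind == "deletion")

    def aligned_read_bases(self) -> int:
        """Read bases participating in the alignment (soft clips excluded)."""
        return (
            self.matched_bases()
            + self.mismatched_bases()
            + self.inserted_bases()
        )

    def identity(self) -> float:
        aligned = self.aligned_read_bases()
        return self.matched_bases() / aligned if aligned else 0.0

    def edit_distance(self) -> int:
        return (
            self.mismatched_bases()
            + self.inserted_bases()
            + self.deleted_bases()
        )

    def junctions(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) pairs implied by intron ops (genome targets)."""
        return tuple(
            (o.target_pos, o.target_pos + o.length)
            for o in self.ops
            if o.kind == "intron"
        )

    def base_at(self, pos: int) -> str | None:
        """The read base aligned over target position ``pos``.

        Returns the reference base for matches (caller must supply it if
        needed — here a match is reported as the sentinel "="), the read base
        for mismatches, None when the position is deleted, inside an intron
        op, or outside the alignment span.
        """
        for op in self.ops:
            if op.kind == "insertion":
                continue
            if op.target_pos <= pos < op.target_pos + op.length:
                if op.kind == "match":
                    return "="
                if op.kind == "mismatch":
                    assert op.query_bases is not None
                    return op.query_bases[pos - op.target_pos]
                return None  # deletion or intron
        return None

    def op_state_at(self, pos: int) -> str:
        """Classify target position pos: match | mismatch | deletion |
        intron | uncovered."""
        for op in self.ops:
            if op.kind == "insertion":
                continue
            if op.target_pos <= pos < op.target_pos + op.length:
                return op.kind
        return "uncovered"


@dataclass
class VariantRecord:
    """A single-nucleotide difference; the unit of phasing.

    pos0 is 0-based internally; VCF I/O converts to/from 1-based POS.
    """

    chrom: str
    pos0: int
    ref_allele: str
    alt_allele: str
    qual: float = 0.0
    phase_set: str | None = None
    genotype: str | None = None
    caller: str = "."

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("VariantRecord is single-nucleotide only")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos0, self.alt_allele)


# ---------------------------------------------------------------------------
# Genome access helpers
# ---------------------------------------------------------------------------


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] from a dict of strings or pyfaidx."""
    seq = str(genome[chrom][start:end]).upper()
    if len(seq) != end - start:
        raise ValueError(
            f"interval {chrom}:{start}-{end} extends beyond chromosome end"
        )
    return seq


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def transcript_sequence(genome, model: TranscriptModel) -> str:
    """Spliced transcript sequence, 5'→3' (reverse-complemented for minus
    strand)."""
    seq = "".join(fetch_seq(genome, e.chrom, e.start, e.end) for e in model.exons)
    return reverse_complement(seq) if model.strand == "-" else seq


def read_fasta(path) -> dict[str, str]:
    """Read an (uncompressed) FASTA into a dict of upper-case strings."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(path, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise ValueError(f"malformed GTF attribute at line {lineno}: {chunk!r}")
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> dict[str, list[TranscriptModel]]:
    """Read exon features from a GTF into gene_id → [TranscriptModel].

    GTF is 1-based closed; exons are converted to 0-based half-open.  Exons
    of each transcript are sorted; transcripts are grouped by gene.  Missing
    transcript_id/gene_id or mixed strands within a transcript are hard
    errors naming the offending line.
    """
    exons: dict[str, list[GenomeInterval]] = {}
    genes: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line {lineno}: {line!r}")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields[:9]
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr, lineno)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise ValueError(
                    f"GTF line {lineno}: exon missing transcript_id/gene_id"
                )
            tid, gid = attrs["transcript_id"], attrs["gene_id"]
            interval = GenomeInterval(chrom, int(start) - 1, int(end), strand)
            if tid in exons and exons[tid][0].strand != strand:
                raise ValueError(
                    f"GTF line {lineno}: transcript {tid} has exons on "
                    "mixed strands"
                )
            exons.setdefault(tid, []).append(interval)
            genes[tid] = gid
    if n_lines == 0:
        logger.warning("GTF %s contains no feature lines", path)
    result: dict[str, list[TranscriptModel]] = {}
    for tid, exon_list in exons.items():
        model = TranscriptModel(tid, genes[tid], exon_list, source="annotated")
        result.setdefault(genes[tid], []).append(model)
    return result


def write_gtf(path, isoforms: Sequence[TranscriptModel]) -> None:
    """Write transcript and exon features (0-based half-open → 1-based
    closed)."""
    with open(path, "w") as fh:
        for model in isoforms:
            attrs = (
                f'gene_id "{model.gene_id}"; '
                f'transcript_id "{model.transcript_id}";'
            )
            fh.write(
                "\t".join(
                    [
                        model.chrom,
                        "haplotx",
                        "transcript",
                        str(model.start + 1),
                        str(model.end),
                        ".",
                        model.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for exon in model.exons:
                fh.write(
                    "\t".join(
                        [
                            model.chrom,
                            "haplotx",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            model.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------


def write_bed12(path, isoforms: Sequence[TranscriptModel]) -> None:
    """Write isoforms as BED12, name = "<transcript_id>_<gene_id>"."""
    with open(path, "w") as fh:
        for model in isoforms:
            sizes = ",".join(str(len(e)) for e in model.exons) + ","
            starts = ",".join(str(e.start - model.start) for e in model.exons) + ","
            fh.write(
                "\t".join(
                    [
                        model.chrom,
                        str(model.start),
                        str(model.end),
                        f"{model.transcript_id}_{model.gene_id}",
                        "1000",
                        model.strand,
                        str(model.start),
                        str(model.end),
                        "0",
                        str(len(model.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path) -> list[TranscriptModel]:
    """Read BED12 back into TranscriptModels.

    The name field is split on its last underscore into transcript_id and
    gene_id, so gene ids must not contain underscores for a lossless
    round-trip.
    """
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomeInterval(chrom, chrom_start + s, chrom_start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            tid, _, gid = name.rpartition("_")
            if not tid:
                tid, gid = name, "."
            models.append(TranscriptModel(tid, gid, exons, source="annotated"))
    return models


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------

_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S, _CIG_H = 0, 1, 2, 3, 4, 5
_CIG_EQ, _CIG_X = 7, 8


def _ops_from_pysam(
    read: pysam.AlignedSegment, target_kind: str, reference
) -> tuple[list[AlnOp], list[GenomeInterval]]:
    cigar = read.cigartuples or []
    query = read.query_sequence or ""
    strand = "-" if read.is_reverse else "+"
    has_m = any(op == _CIG_M and ln > 0 for op, ln in cigar)
    refmap: dict[int, str] = {}
    if has_m:
        if reference is not None:
            ref_name = read.reference_name
            seg = fetch_seq(
                reference, ref_name, read.reference_start, read.reference_end
            )
            refmap = {
                read.reference_start + i: seg[i] for i in range(len(seg))
            }
        elif read.has_tag("MD"):
            for qpos, rpos, base in read.get_aligned_pairs(with_seq=True):
                if rpos is not None and base is not None:
                    refmap[rpos] = base.upper()
        else:
            raise ValueError(
                f"read {read.query_name}: cannot resolve mismatches "
                "(no MD tag, no =/X ops, no reference sequence supplied)"
            )

    ops: list[AlnOp] = []
    blocks: list[GenomeInterval] = []
    qpos, rpos = 0, read.reference_start
    block_start = rpos

    def emit(kind: str, length: int, target_pos: int, bases: str | None = None):
        if length <= 0:
            return
        if ops and ops[-1].kind == kind and kind in ("match",) and (
            ops[-1].target_pos + ops[-1].length == target_pos
        ):
            ops[-1] = replace(ops[-1], length=ops[-1].length + length)
        else:
            ops.append(AlnOp(kind, length, target_pos, bases))

    for op, ln in cigar:
        if op in (_CIG_S, _CIG_H):
            if op == _CIG_S:
                qpos += ln
        elif op == _CIG_EQ:
            emit("match", ln, rpos)
            qpos += ln
            rpos += ln
        elif op == _CIG_X:
            emit("mismatch", ln, rpos, query[qpos : qpos + ln] if query else None)
            qpos += ln
            rpos += ln
        elif op == _CIG_M:
            run_kind, run_start_r, run_start_q = None, rpos, qpos
            for i in range(ln):
                qb = query[qpos + i] if query else "N"
                rb = refmap.get(rpos + i)
                kind = "match" if (rb is not None and qb.upper() == rb) else "mismatch"
                if kind != run_kind:
                    if run_kind is not None:
                        length = (rpos + i) - run_start_r
                        emit(
                            run_kind,
                            length,
                            run_start_r,
                            query[run_start_q : run_start_q + length]
                            if (query and run_kind == "mismatch")
                            else None,
                        )
                    run_kind, run_start_r, run_start_q = kind, rpos + i, qpos + i
            if run_kind is not None:
                length = (rpos + ln) - run_start_r
                emit(
                    run_kind,
                    length,
                    run_start_r,
                    query[run_start_q : run_start_q + length]
                    if (query and run_kind == "mismatch")
                    else None,
                )
            qpos += ln
            rpos += ln
        elif op == _CIG_I:
            emit("insertion", ln, rpos, query[qpos : qpos + ln] if query else None)
            qpos += ln
        elif op == _CIG_D:
            emit("deletion", ln, rpos)
            rpos += ln
        elif op == _CIG_N:
            if target_kind == "transcript":
                raise ValueError(
                    f"read {read.query_name}: intron (N) op in a "
                    "transcriptome alignment"
                )
            if rpos > block_start:
                blocks.append(
                    GenomeInterval(read.reference_name, block_start, rpos, strand)
                )
            emit("intron", ln, rpos)
            rpos += ln
            block_start = rpos
        else:
            raise ValueError(f"unsupported CIGAR op code {op}")
    if rpos > block_start:
        blocks.append(GenomeInterval(read.reference_name, block_start, rpos, strand))
    return ops, blocks


def read_alignments(
    path, target_kind: str, reference=None, keep_unmapped: bool = False
) -> Iterator[ReadAlignment]:
    """Stream ReadAlignments from a SAM/BAM file.

    ``target_kind`` is "genome" or "transcript"; intron (N) ops are only
    legal against the genome.  Mismatch positions are resolved from =/X
    CIGAR ops, the MD tag, or an explicitly supplied ``reference`` — if none
    is available for an M op the record is a hard error.  Secondary and
    supplementary records are retained but flagged.
    """
    if target_kind not in ("genome", "transcript"):
        raise ValueError(f"bad target_kind {target_kind!r}")
    save = pysam.set_verbosity(0)
    mode = "rb" if str(path).endswith(".bam") else "r"
    try:
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for read in fh:
                if read.is_unmapped:
                    if keep_unmapped:
                        yield ReadAlignment(
                            read.query_name, "*", target_kind, [], [], 0
                        )
                    continue
                ops, blocks = _ops_from_pysam(read, target_kind, reference)
                tags = {}
                for tag in ("HP", "PS"):
                    if read.has_tag(tag):
                        tags[tag] = read.get_tag(tag)
                yield ReadAlignment(
                    read_id=read.query_name,
                    target_id=read.reference_name,
                    target_kind=target_kind,
                    blocks=blocks,
                    ops=ops,
                    mapq=read.mapping_quality,
                    strand="-" if read.is_reverse else "+",
                    is_secondary=read.is_secondary,
                    is_supplementary=read.is_supplementary,
                    tags=tags,
                )
    finally:
        pysam.set_verbosity(save)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class VcfReadStats:
    n_records: int = 0
    n_kept: int = 0
    n_skipped: int = 0


def read_vcf(path, caller: str | None = None, stats: VcfReadStats | None = None) -> list[VariantRecord]:
    """Read SNV records from a VCF 4.x file.

    Multi-allelic records are split into one VariantRecord per ALT; records
    whose REF or ALT is not a single nucleotide are skipped with a warning
    and counted in ``stats``.  pos0 = POS − 1; phase_set comes from the PS
    format tag, genotype from GT (phased genotypes keep the "|" separator).
    """
    stats = stats if stats is not None else VcfReadStats()
    records: list[VariantRecord] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                stats.n_records += 1
                phase_set = None
                genotype = None
                if rec.samples:
                    sample = rec.samples[0]
                    ps = sample.get("PS")
                    if ps is not None:
                        phase_set = str(ps)
                    gt = sample.get("GT")
                    if gt is not None and gt != (None,):
                        sep = "|" if sample.phased else "/"
                        genotype = sep.join(
                            "." if a is None else str(a) for a in gt
                        )
                for alt in rec.alts or ():
                    if (
                        rec.ref is None
                        or len(rec.ref) != 1
                        or len(alt) != 1
                        or alt not in "ACGT"
                        or rec.ref not in "ACGT"
                    ):
                        stats.n_skipped += 1
                        logger.warning(
                            "skipping non-SNV record %s:%s %s>%s",
                            rec.chrom,
                            rec.pos,
                            rec.ref,
                            alt,
                        )
                        continue
                    stats.n_kept += 1
                    records.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos0=rec.pos - 1,
                            ref_allele=rec.ref,
                            alt_allele=alt,
                            qual=float(rec.qual) if rec.qual is not None else 0.0,
                            phase_set=phase_set,
                            genotype=genotype,
                            caller=caller or Path(str(path)).stem,
                        )
                    )
    finally:
        pysam.set_verbosity(save)
    return records


def write_vcf(
    path,
    records: Sequence[VariantRecord],
    contigs: Mapping[str, int],
    iso_map: Mapping[tuple[str, int, str], Sequence[str]] | None = None,
) -> None:
    """Write VariantRecords to VCF 4.2.

    ``iso_map`` maps (chrom, pos0, alt) → isoform names carried in the
    custom INFO key ISO.  A single sample column carries GT/PS when records
    have genotype/phase-set information.
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=ISO,Number=.,Type=String,Description="Isoforms carrying this variant">')
    header.add_line('##INFO=<ID=CALLER,Number=1,Type=String,Description="Variant caller provenance">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    has_sample = any(r.genotype or r.phase_set for r in records)
    if has_sample:
        header.add_sample("SAMPLE")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos0, r.alt_allele)):
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos0,
                stop=rec.pos0 + 1,
                alleles=(rec.ref_allele, rec.alt_allele),
                qual=rec.qual,
            )
            vrec.info["CALLER"] = rec.caller.replace(" ", "_")
            if iso_map:
                isos = iso_map.get(rec.key())
                if isos:
                    vrec.info["ISO"] = ",".join(isos)
            if has_sample:
                sample = vrec.samples["SAMPLE"]
                if rec.genotype:
                    phased = "|" in rec.genotype
                    alleles = tuple(
                        None if a == "." else int(a)
                        for a in rec.genotype.replace("|", "/").split("/")
                    )
                    sample["GT"] = alleles
                    sample.phased = phased
                if rec.phase_set is not None:
                    sample["PS"] = int(rec.phase_set)
            out.write(vrec)


# ---------------------------------------------------------------------------
# Combined isoform output
# ---------------------------------------------------------------------------


def write_isoforms(
    isoforms: Sequence[TranscriptModel],
    bed_path,
    gtf_path,
    fasta_path,
    genome,
) -> None:
    """Write the final isoform set as BED12 + GTF + spliced FASTA.

    FASTA sequences are exon concatenations, reverse-complemented on the
    minus strand; sequence names follow the BED12 name convention.  An exon
    beyond the chromosome end is a hard error.
    """
    for model in isoforms:
        if model.end > chrom_length(genome, model.chrom):
            raise ValueError(
                f"isoform {model.transcript_id}: exon beyond end of "
                f"{model.chrom}"
            )
    write_bed12(bed_path, isoforms)
    write_gtf(gtf_path, isoforms)
    seqs = {
        f"{m.transcript_id}_{m.gene_id}": transcript_sequence(genome, m)
        for m in isoforms
    }
    write_fasta(fasta_path, seqs)
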