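"""Annotation-reliant read-to-transcript assignment.

Long reads are first aligned (ungapped) to the annotated transcriptome.
Each read's candidate transcripts are screened with two fidelity rules
before the read may support an annotated isoform:

* the *stringent* rule — at least 80% of aligned read bases must match the
  transcript and the alignment must span into the first and last exons
  (25 bp, or the whole exon when shorter);
* the *splice* rule — around every covered exon–exon junction of the
  transcript, at least 4 of the 6 flanking bases (3 per side) must be
  matches and no insertion or deletion longer than 3 bp may touch the
  junction window.

Reads passing both on some candidate support that transcript; annotated
transcripts with enough supporting reads enter the final isoform set, and
everything else is handed to novel-isoform collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomeInterval, ReadAlignment, TranscriptModel


@dataclass(frozen=True)
class FidelityConfig:
    """Thresholds for the stringent/splice fidelity rules.

    All thresholds are inclusive (≥ min_identity, ≥ min_flank_matches,
    indels ≤ max_splice_indel_bp pass).
    """

    min_identity: float = 0.80
    end_span_bp: int = 25
    splice_flank_bp: int = 3
    min_flank_matches: int = 4
    max_splice_indel_bp: int = 3
    min_support: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_flank_matches > 2 * self.splice_flank_bp:
            raise ValueError("min_flank_matches exceeds window size")


@dataclass
class ReadAssignment:
    read_id: str
    transcript_id: str
    passed_stringent: bool
    passed_check_splice: bool


def select_best_transcript_alignments(
    alignments: Iterable[ReadAlignment],
) -> dict[str, list[ReadAlignment]]:
    """Order each read's transcriptome alignments into a candidate list.

    Candidates are sorted by mapping quality (descending); ties broken by
    fewer mismatches+indels, then lexicographic transcript id, so the order
    is deterministic.
    """
    per_read: dict[str, list[ReadAlignment]] = {}
    for aln in alignments:
        if aln.target_kind != "transcript":
            raise ValueError("expected transcriptome alignments")
        per_read.setdefault(aln.read_id, []).append(aln)
    for read_id, alns in per_read.items():
        alns.sort(key=lambda a: (-a.mapq, a.edit_distance(), a.target_id))
    return per_read


def _covered_span(aln: ReadAlignment) -> tuple[int, int]:
    return aln.target_start, aln.target_end


def check_stringent(
    aln: ReadAlignment,
    transcript_length: int,
    first_exon: GenomeInterval,
    last_exon: GenomeInterval,
    cfg: FidelityConfig,
) -> bool:
    """Identity + terminal-span check against one transcript.

    ``first_exon``/``last_exon`` are the transcript's 5' and 3' exons.  The
    alignment must span into the terminal exons: it may leave at most
    min(end_span_bp, exon length) bases uncovered at each transcript end,
    measured in transcript coordinates (a read starting 30 bp into a long
    first exon misses 30 > 25 and fails).  Identity is matched bases over
    aligned read bases (soft clips excluded).  Both thresholds inclusive.
    """
    if len(first_exon) > transcript_length or len(last_exon) > transcript_length:
        raise ValueError("transcript_length inconsistent with exon chain")
    if aln.identity() < cfg.min_identity:
        return False
    span_start, span_end = _covered_span(aln)
    allow_first = min(cfg.end_span_bp, len(first_exon))
    allow_last = min(cfg.end_span_bp, len(last_exon))
    missed_5p = span_start
    missed_3p = transcript_length - span_end
    return missed_5p <= allow_first and missed_3p <= allow_last


def check_splice(
    aln: ReadAlignment,
    junction_positions_tx: Sequence[int],
    cfg: FidelityConfig,
) -> bool:
    """Per-junction flank-match and indel check.

    A junction at transcript offset j is checked when the alignment fully
    spans its window [j - flank, j + flank); junctions outside the aligned
    span (truncated reads) impose no constraint.  Within a checked window at
    least ``min_flank_matches`` of the 2·flank bases must be matches, and no
    insertion/deletion longer than ``max_splice_indel_bp`` may overlap the
    window.
    """
    flank = cfg.splice_flank_bp
    span_start, span_end = _covered_span(aln)
    for j in junction_positions_tx:
        w_start, w_end = j - flank, j + flank
        if w_start < span_start or w_end > span_end:
            continue  # junction not (fully) covered: no constraint
        matched = 0
        for op in aln.ops:
            if op.kind == "match":
                matched += max(
                    0, min(op.target_pos + op.length, w_end) - max(op.target_pos, w_start)
                )
            elif op.kind == "insertion":
                if op.length > cfg.max_splice_indel_bp and w_start <= op.target_pos <= w_end:
                    return False
            elif op.kind == "deletion":
                if op.length > cfg.max_splice_indel_bp and (
                    op.target_pos < w_end and op.target_pos + op.length > w_start
                ):
                    return False
        if matched < cfg.min_flank_matches:
            return False
    return True


def check_fidelity(
    aln: ReadAlignment, transcript: TranscriptModel, cfg: FidelityConfig
) -> tuple[bool, bool]:
    """Apply both rules of one alignment against its transcript model."""
    tx_exons = transcript.exons_in_transcript_order()
    stringent = check_stringent(
        aln, transcript.length, tx_exons[0], tx_exons[-1], cfg
    )
    splice = check_splice(aln, transcript.junction_positions_tx(), cfg)
    return stringent, splice


def assign_reads(
    candidates: Mapping[str, Sequence[ReadAlignment]],
    transcripts: Mapping[str, TranscriptModel],
    cfg: FidelityConfig,
) -> tuple[list[ReadAssignment], set[str]]:
    """Assign each read to its first candidate passing both fidelity rules.

    Reads with no passing candidate go to the unassigned set; together the
    two outputs partition the input read ids.
    """
    assignments: list[ReadAssignment] = []
    unassigned: set[str] = set()
    for read_id in sorted(candidates):
        assigned = False
        for aln in candidates[read_id]:
            model = transcripts.get(aln.target_id)
            if model is None:
                continue
            stringent, splice = check_fidelity(aln, model, cfg)
            if stringent and splice:
                assignments.append(
                    ReadAssignment(read_id, aln.target_id, True, True)
                )
                assigned = True
                break
        if not assigned:
            unassigned.add(read_id)
    return assignments, unassigned


def supported_annotated_isoforms(
    assignments: Iterable[ReadAssignment],
    transcripts: Mapping[str, TranscriptModel],
    cfg: FidelityConfig,
) -> list[tuple[TranscriptModel, set[str]]]:
    """Annotated transcripts with ≥ min_support assigned reads (inclusive),
    with their supporting read-id sets, in deterministic id order."""
    support: dict[str, set[str]] = {}
    for asn in assignments:
        support.setdefault(asn.transcript_id, set()).add(asn.read_id)
    kept = []
    for tid in sorted(support):
        reads = support[tid]
        if len(reads) >= cfg.min_support:
            kept.append((transcripts[tid], reads))
    return kept
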