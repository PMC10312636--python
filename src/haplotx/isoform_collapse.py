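"""Novel-isoform detection from genome alignments of unassigned reads.

The collapse procedure:

1. *splice-site correction* — each read splice site without support in the
   evidence set (annotation, short-read junctions, or well-supported
   long-read junctions) is moved to the nearest evidence site within a
   window; reads with uncorrectable sites are excluded from model building;
2. *junction-chain grouping* — corrected reads with identical junction
   chains form a group; single-exon reads group by overlap locus;
3. *end calling* — read starts and ends in each group are clustered
   (single linkage) and each start/end cluster pair becomes a first-pass
   isoform;
4. *re-assignment* — every unassigned read is matched against the first-pass
   models under the same splice-fidelity rules used for annotated
   assignment (the genome alignment is projected through the candidate
   model's exon structure, which for ungapped long-read alignments is an
   exact realignment);
5. *support filtering and merging* — novel models passing the minimum
   supporting read count are merged with the supported annotated isoforms;
   chains identical to a retained annotated transcript collapse onto it,
   and terminal-truncation artifacts (models whose chain is a contiguous
   end-subchain of a better-supported model with a matching far end) are
   absorbed.
"""

from __future__ import annotations

import bisect
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import (
    GenomeInterval,
    ReadAlignment,
    TranscriptModel,
    fetch_seq,
)
from .transcript_assignment import FidelityConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Splice-site evidence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionEvidence:
    """One observed splice junction with its provenance and weight."""

    chrom: str
    donor: int  # intron start, 0-based
    acceptor: int  # intron end (exclusive)
    strand: str
    source: str  # "annotation" | "short_read" | "long_read"
    weight: int = 1

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError("junction donor must precede acceptor")


class SpliceEvidence:
    """Per-chromosome sorted indexes of usable donor and acceptor sites.

    Annotation and short-read sites are always usable; long-read-only sites
    require ``min_long_read_support`` distinct reads before they may anchor
    correction.
    """

    def __init__(
        self,
        evidence: Iterable[JunctionEvidence],
        min_long_read_support: int = 3,
    ) -> None:
        donors: dict[str, set[int]] = defaultdict(set)
        acceptors: dict[str, set[int]] = defaultdict(set)
        lr_donors: Counter = Counter()
        lr_acceptors: Counter = Counter()
        for ev in evidence:
            if ev.source in ("annotation", "short_read"):
                donors[ev.chrom].add(ev.donor)
                acceptors[ev.chrom].add(ev.acceptor)
            elif ev.source == "long_read":
                lr_donors[(ev.chrom, ev.donor)] += ev.weight
                lr_acceptors[(ev.chrom, ev.acceptor)] += ev.weight
            else:
                raise ValueError(f"unknown evidence source {ev.source!r}")
        for (chrom, pos), count in lr_donors.items():
            if count >= min_long_read_support:
                donors[chrom].add(pos)
        for (chrom, pos), count in lr_acceptors.items():
            if count >= min_long_read_support:
                acceptors[chrom].add(pos)
        self._donors = {c: sorted(s) for c, s in donors.items()}
        self._acceptors = {c: sorted(s) for c, s in acceptors.items()}

    def sites(self, chrom: str, side: str) -> list[int]:
        index = self._donors if side == "donor" else self._acceptors
        return index.get(chrom, [])

    def nearest(self, chrom: str, side: str, pos: int, window: int) -> int | None:
        """Nearest usable site within ``window`` bp; ties break to the
        smaller coordinate; exact hits return pos itself."""
        sites = self.sites(chrom, side)
        if not sites:
            return None
        i = bisect.bisect_left(sites, pos)
        best, best_dist = None, window + 1
        for j in (i - 1, i):
            if 0 <= j < len(sites):
                dist = abs(sites[j] - pos)
                if dist < best_dist or (
                    dist == best_dist and best is not None and sites[j] < best
                ):
                    best, best_dist = sites[j], dist
        return best if best_dist <= window else None


def evidence_from_annotation(
    annotation: Mapping[str, Sequence[TranscriptModel]],
) -> list[JunctionEvidence]:
    out = []
    for models in annotation.values():
        for model in models:
            for donor, acceptor in model.junctions():
                out.append(
                    JunctionEvidence(
                        model.chrom, donor, acceptor, model.strand, "annotation"
                    )
                )
    return out


def evidence_from_junction_bed(path) -> list[JunctionEvidence]:
    """Read short-read junction evidence from a BED-like file
    (chrom, donor, acceptor, count[, strand])."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, donor, acceptor = f[0], int(f[1]), int(f[2])
            weight = int(f[3]) if len(f) > 3 and f[3] not in (".", "") else 1
            strand = f[5] if len(f) > 5 else "+"
            out.append(
                JunctionEvidence(chrom, donor, acceptor, strand, "short_read", weight)
            )
    return out


def evidence_from_reads(reads: Iterable[ReadAlignment]) -> list[JunctionEvidence]:
    counts: Counter = Counter()
    strands: dict = {}
    for read in reads:
        for donor, acceptor in read.junctions():
            counts[(read.blocks[0].chrom, donor, acceptor)] += 1
            strands.setdefault((read.blocks[0].chrom, donor, acceptor), read.strand)
    return [
        JunctionEvidence(chrom, d, a, strands[(chrom, d, a)], "long_read", n)
        for (chrom, d, a), n in counts.items()
    ]


# ---------------------------------------------------------------------------
# Correction and grouping
# ---------------------------------------------------------------------------


@dataclass
class CorrectedRead:
    """A genome-aligned read with evidence-corrected splice junctions."""

    read_id: str
    chrom: str
    strand: str
    start: int
    end: int
    junctions: tuple[tuple[int, int], ...]


def correct_splice_sites(
    reads: Iterable[ReadAlignment],
    evidence: SpliceEvidence,
    window: int = 10,
) -> tuple[list[CorrectedRead], set[str]]:
    """Snap read splice sites to the nearest evidence site within ``window``.

    Donors and acceptors are corrected independently; a read with any site
    having no evidence within the window (or whose corrected junction
    degenerates, donor ≥ acceptor) is flagged uncorrectable and excluded
    from model building.
    """
    corrected: list[CorrectedRead] = []
    flagged: set[str] = set()
    for read in reads:
        chrom = read.blocks[0].chrom
        new_junctions = []
        ok = True
        for donor, acceptor in read.junctions():
            new_donor = evidence.nearest(chrom, "donor", donor, window)
            new_acceptor = evidence.nearest(chrom, "acceptor", acceptor, window)
            if new_donor is None or new_acceptor is None or new_donor >= new_acceptor:
                ok = False
                break
            new_junctions.append((new_donor, new_acceptor))
        if not ok:
            flagged.add(read.read_id)
            continue
        if any(
            nxt[0] <= cur[1] for cur, nxt in zip(new_junctions, new_junctions[1:])
        ):
            flagged.add(read.read_id)  # corrected junctions overlap
            continue
        corrected.append(
            CorrectedRead(
                read_id=read.read_id,
                chrom=chrom,
                strand=read.strand,
                start=read.target_start,
                end=read.target_end,
                junctions=tuple(new_junctions),
            )
        )
    return corrected, flagged


def group_by_junction_chain(
    corrected: Sequence[CorrectedRead],
) -> dict[tuple, list[CorrectedRead]]:
    """Group reads by exact junction-chain equality.

    Multi-exon keys are (chrom, junction chain).  Single-exon reads form one
    group per overlap-connected locus, keyed (chrom, "mono", locus start).
    A chain that is a strict prefix of another is a distinct group — no
    containment merging happens here.
    """
    groups: dict[tuple, list[CorrectedRead]] = defaultdict(list)
    mono: dict[str, list[CorrectedRead]] = defaultdict(list)
    for read in corrected:
        if read.junctions:
            groups[(read.chrom, read.junctions)].append(read)
        else:
            mono[read.chrom].append(read)
    for chrom, reads in mono.items():
        reads.sort(key=lambda r: (r.start, r.end, r.read_id))
        locus_start, locus_end, members = None, None, []
        for read in reads:
            if locus_end is None or read.start < locus_end:
                members.append(read)
                locus_start = read.start if locus_start is None else locus_start
                locus_end = read.end if locus_end is None else max(locus_end, read.end)
            else:
                groups[(chrom, "mono", locus_start)] = members
                locus_start, locus_end, members = read.start, read.end, [read]
        if members:
            groups[(chrom, "mono", locus_start)] = members
    return dict(groups)


def _single_linkage_clusters(values: Sequence[int], gap: int) -> list[list[int]]:
    clusters: list[list[int]] = []
    for v in sorted(values):
        if clusters and v - clusters[-1][-1] <= gap:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return clusters


def _representative(positions: Sequence[int], outermost: str) -> int:
    """Most-supported position; ties go outermost (min for starts,
    max for ends)."""
    counts = Counter(positions)
    best_count = max(counts.values())
    candidates = [p for p, c in counts.items() if c == best_count]
    return min(candidates) if outermost == "min" else max(candidates)


@dataclass
class FirstPassIsoform:
    model: TranscriptModel
    supporting_read_ids: set[str]
    tss: int
    tes: int


def call_ends(
    group: Sequence[CorrectedRead], end_window: int = 100
) -> list[tuple[int, int, set[str]]]:
    """Cluster read 5' starts and 3' ends and emit (tss, tes, read ids)
    per occupied (start-cluster, end-cluster) pair.

    Starts and ends are clustered independently by single linkage with gap ≤
    ``end_window``; the representative position of a cluster is its
    most-supported value (ties → outermost).
    """
    if not group:
        return []
    start_clusters = _single_linkage_clusters([r.start for r in group], end_window)
    end_clusters = _single_linkage_clusters([r.end for r in group], end_window)

    def cluster_id(clusters: list[list[int]], value: int) -> int:
        for i, cl in enumerate(clusters):
            if cl[0] <= value <= cl[-1]:
                return i
        raise AssertionError("value outside its clusters")

    pairs: dict[tuple[int, int], list[CorrectedRead]] = defaultdict(list)
    for read in group:
        pairs[
            (cluster_id(start_clusters, read.start), cluster_id(end_clusters, read.end))
        ].append(read)
    out = []
    for key in sorted(pairs):
        members = pairs[key]
        tss = _representative([r.start for r in members], "min")
        tes = _representative([r.end for r in members], "max")
        out.append((tss, tes, {r.read_id for r in members}))
    return out


def _infer_strand(
    genome, chrom: str, junctions: Sequence[tuple[int, int]], fallback: str
) -> str:
    """GT–AG majority vote over junction dinucleotides; falls back to the
    alignment strand when the vote is tied or there are no junctions."""
    plus = minus = 0
    for donor, acceptor in junctions:
        try:
            left = fetch_seq(genome, chrom, donor, donor + 2)
            right = fetch_seq(genome, chrom, acceptor - 2, acceptor)
        except (ValueError, KeyError):
            continue
        if left == "GT" and right == "AG":
            plus += 1
        elif left == "CT" and right == "AC":
            minus += 1
    if plus > minus:
        return "+"
    if minus > plus:
        return "-"
    return fallback


def _exons_from_chain(
    chrom: str,
    start: int,
    end: int,
    junctions: Sequence[tuple[int, int]],
    strand: str,
) -> list[GenomeInterval]:
    bounds = [start]
    for donor, acceptor in junctions:
        bounds.extend([donor, acceptor])
    bounds.append(end)
    exons = []
    for s, e in zip(bounds[::2], bounds[1::2]):
        exons.append(GenomeInterval(chrom, s, e, strand))
    return exons


def build_firstpass(
    groups: Mapping[tuple, Sequence[CorrectedRead]],
    genome,
    end_window: int = 100,
) -> list[FirstPassIsoform]:
    """Build first-pass isoform models from junction-chain groups."""
    isoforms: list[FirstPassIsoform] = []
    for key in sorted(groups, key=str):
        group = groups[key]
        chrom = group[0].chrom
        junctions = group[0].junctions
        fallback = Counter(r.strand for r in group).most_common(1)[0][0]
        strand = _infer_strand(genome, chrom, junctions, fallback)
        for i, (tss, tes, read_ids) in enumerate(call_ends(group, end_window)):
            if junctions and (tss >= junctions[0][0] or tes <= junctions[-1][1]):
                continue  # degenerate ends (should not arise from real reads)
            name = f"iso.{chrom}.{tss}.{tes}.j{len(junctions)}.{i}"
            model = TranscriptModel(
                transcript_id=name,
                gene_id=f"locus.{chrom}.{junctions[0][0] if junctions else tss}",
                exons=_exons_from_chain(chrom, tss, tes, junctions, strand),
                source="novel",
            )
            isoforms.append(FirstPassIsoform(model, set(read_ids), tss, tes))
    return isoforms


# ---------------------------------------------------------------------------
# Re-assignment of reads to first-pass models
# ---------------------------------------------------------------------------


def _is_contiguous_subchain(
    sub: Sequence[tuple[int, int]], chain: Sequence[tuple[int, int]]
) -> bool:
    if not sub:
        return True
    n, m = len(sub), len(chain)
    for i in range(m - n + 1):
        if tuple(chain[i : i + n]) == tuple(sub):
            return True
    return False


def evaluate_read_on_model(
    read: ReadAlignment,
    model: TranscriptModel,
    cfg: FidelityConfig,
) -> tuple[bool, bool, int]:
    """Apply the stringent and splice fidelity rules to a genome-aligned
    read against a transcript model, by projecting the alignment through
    the model's exon structure.

    Returns (stringent_ok, splice_ok, matched bases inside model exons).
    Read bases aligned outside the model's exons count against identity;
    aligned footprint inside a model intron beyond the splice-indel
    allowance fails that junction (it corresponds to an insertion at the
    junction in transcript coordinates).
    """
    exons = model.exons
    flank = cfg.splice_flank_bp

    def exon_overlap(start: int, end: int) -> int:
        return sum(
            max(0, min(end, e.end) - max(start, e.start)) for e in exons
        )

    matched_in = 0
    first_pos = None
    last_pos = None
    for op in read.ops:
        if op.kind not in ("match", "mismatch"):
            continue
        ov = 0
        for e in exons:
            lo, hi = max(op.target_pos, e.start), min(op.target_pos + op.length, e.end)
            if lo < hi:
                ov += hi - lo
                first_pos = lo if first_pos is None else min(first_pos, lo)
                last_pos = hi - 1 if last_pos is None else max(last_pos, hi - 1)
        if op.kind == "match":
            matched_in += ov
    aligned = read.aligned_read_bases()
    if aligned == 0 or first_pos is None:
        return False, False, 0

    identity = matched_in / aligned
    tx_a = model.genome_to_tx(first_pos)
    tx_b = model.genome_to_tx(last_pos)
    assert tx_a is not None and tx_b is not None
    tx_start, tx_end = min(tx_a, tx_b), max(tx_a, tx_b) + 1
    tx_exons = model.exons_in_transcript_order()
    allow_first = min(cfg.end_span_bp, len(tx_exons[0]))
    allow_last = min(cfg.end_span_bp, len(tx_exons[-1]))
    stringent = (
        identity >= cfg.min_identity
        and tx_start <= allow_first
        and (model.length - tx_end) <= allow_last
    )

    span_lo, span_hi = read.target_start, read.target_end
    splice_ok = True
    for donor, acceptor in model.junctions():
        w_left = (donor - flank, donor)
        w_right = (acceptor, acceptor + flank)
        if span_lo > w_left[0] or span_hi < w_right[1]:
            continue  # junction not fully covered by the read span
        matched = 0
        for op in read.ops:
            if op.kind == "match":
                for lo, hi in (w_left, w_right):
                    matched += max(
                        0, min(op.target_pos + op.length, hi) - max(op.target_pos, lo)
                    )
            elif op.kind == "insertion":
                if (
                    op.length > cfg.max_splice_indel_bp
                    and w_left[0] <= op.target_pos <= w_right[1]
                ):
                    splice_ok = False
            elif op.kind == "deletion":
                if op.length > cfg.max_splice_indel_bp and (
                    (op.target_pos < w_left[1] and op.target_pos + op.length > w_left[0])
                    or (op.target_pos < w_right[1] and op.target_pos + op.length > w_right[0])
                ):
                    splice_ok = False
        # aligned footprint inside the model intron == insertion at junction
        intron_overlap = sum(
            max(0, min(op.target_pos + op.length, acceptor) - max(op.target_pos, donor))
            for op in read.ops
            if op.kind in ("match", "mismatch", "deletion")
        )
        if intron_overlap > cfg.max_splice_indel_bp:
            splice_ok = False
        if matched < cfg.min_flank_matches:
            splice_ok = False
        if not splice_ok:
            break
    return stringent, splice_ok, matched_in


def assign_to_firstpass(
    reads: Sequence[ReadAlignment],
    corrected: Mapping[str, CorrectedRead],
    firstpass: Sequence[FirstPassIsoform],
    cfg: FidelityConfig,
) -> tuple[dict[str, set[str]], set[str], int]:
    """Re-assign every read to its best passing first-pass model.

    A model is a candidate when the read's corrected junction chain is a
    contiguous subchain of the model's chain (single-exon reads are
    candidates for overlapping models).  Among candidates passing both
    fidelity rules the one with the most matched bases wins (ties →
    transcript id).  Returns (supports, unassigned read ids, number of
    reads that moved out of the group that built their model).
    """
    by_chain: dict[tuple, str] = {
        fp.model.chain_key(): fp.model.transcript_id
        for fp in firstpass
        if fp.model.junctions()
    }
    models = {fp.model.transcript_id: fp.model for fp in firstpass}
    supports: dict[str, set[str]] = {tid: set() for tid in models}
    unassigned: set[str] = set()
    moved = 0
    for read in sorted(reads, key=lambda r: r.read_id):
        cread = corrected.get(read.read_id)
        if cread is None:
            unassigned.add(read.read_id)
            continue
        best = None
        for fp in firstpass:
            model = fp.model
            if model.chrom != cread.chrom:
                continue
            if cread.junctions:
                if not _is_contiguous_subchain(cread.junctions, model.junctions()):
                    continue
            else:
                if not (cread.start < model.end and model.start < cread.end):
                    continue
            stringent, splice, matched = evaluate_read_on_model(read, model, cfg)
            if stringent and splice:
                key = (-matched, model.transcript_id)
                if best is None or key < best[0]:
                    best = (key, model.transcript_id)
        if best is None:
            unassigned.add(read.read_id)
            continue
        supports[best[1]].add(read.read_id)
        own = by_chain.get((cread.chrom, cread.junctions))
        if own is not None and own != best[1]:
            moved += 1
    return supports, unassigned, moved


# ---------------------------------------------------------------------------
# Final merging
# ---------------------------------------------------------------------------


def finalize(
    firstpass: Sequence[FirstPassIsoform],
    supports: Mapping[str, set[str]],
    annotated_supported: Sequence[tuple[TranscriptModel, set[str]]],
    min_support: int = 3,
    filter_subchains: bool = True,
    end_window: int = 100,
) -> list[tuple[TranscriptModel, set[str]]]:
    """Merge supported novel models with supported annotated isoforms.

    Novel models need ≥ ``min_support`` reads.  A novel multi-exon chain
    identical to a retained annotated transcript collapses onto the
    annotated entry (reads merged).  With ``filter_subchains``, a novel
    model whose chain is a contiguous terminal subchain of a
    better-supported final model — with its far end within ``end_window``
    of that model's corresponding end and its near end inside the model's
    span — is treated as a truncation artifact and absorbed.  A single-exon
    novel model fully contained in an exon of a multi-exon final model is
    suppressed.
    """
    final: list[tuple[TranscriptModel, set[str]]] = [
        (model, set(reads)) for model, reads in annotated_supported
    ]
    annotated_chains = {
        model.chain_key(): i
        for i, (model, _reads) in enumerate(final)
        if model.junctions()
    }

    novel: list[tuple[TranscriptModel, set[str]]] = []
    for fp in sorted(firstpass, key=lambda f: f.model.transcript_id):
        reads = supports.get(fp.model.transcript_id, set())
        if len(reads) < min_support:
            continue
        chain = fp.model.chain_key()
        if fp.model.junctions() and chain in annotated_chains:
            idx = annotated_chains[chain]
            final[idx] = (final[idx][0], final[idx][1] | reads)
            continue
        novel.append((fp.model, set(reads)))

    if filter_subchains:
        keep: list[tuple[TranscriptModel, set[str]]] = []
        others = final + novel
        for model, reads in novel:
            parent = (
                _best_parent(model, len(reads), others, end_window)
                if model.junctions()
                else None
            )
            if parent is not None:
                parent[1].update(reads)
                continue
            keep.append((model, reads))
        novel = keep

    # suppress single-exon fragments inside final multi-exon exons
    multi = [m for m, _ in final + novel if m.junctions()]
    kept_novel = []
    for model, reads in novel:
        if not model.junctions():
            exon = model.exons[0]
            contained = any(
                e.chrom == exon.chrom and e.start <= exon.start and exon.end <= e.end
                for big in multi
                for e in big.exons
            )
            if contained:
                continue
        kept_novel.append((model, reads))

    result = final + kept_novel
    result.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].transcript_id))
    return result


def _is_strict_terminal_subchain(
    sub: Sequence[tuple[int, int]], chain: Sequence[tuple[int, int]]
) -> str | None:
    """Return "prefix"/"suffix" when sub is a strict terminal contiguous
    subchain of chain, else None."""
    n, m = len(sub), len(chain)
    if n == 0 or n >= m:
        return None
    if tuple(chain[:n]) == tuple(sub):
        return "prefix"
    if tuple(chain[m - n :]) == tuple(sub):
        return "suffix"
    return None


def _best_parent(
    model: TranscriptModel,
    n_reads: int,
    others: Sequence[tuple[TranscriptModel, set[str]]],
    end_window: int,
) -> tuple[TranscriptModel, set[str]] | None:
    """The model this one is a truncation artifact of, if any.

    Three artifact shapes, all requiring the candidate parent to dominate
    in support (ties break to the lexicographically smaller id so two
    equal-support duplicates never absorb each other):

    * suffix subchain — right ends agree within ``end_window``, left end
      inside the parent's span (a 5'-truncated plus-strand read pile);
    * prefix subchain — mirrored;
    * equal chain — span contained in the parent's span with
      ``end_window`` slack (a split end-cluster of truncated reads).
    """
    best = None
    for other, other_reads in others:
        if other.transcript_id == model.transcript_id or other.chrom != model.chrom:
            continue
        dominates = len(other_reads) > n_reads or (
            len(other_reads) == n_reads
            and other.transcript_id < model.transcript_id
        )
        if not dominates:
            continue
        if model.junctions() == other.junctions():
            if other.source == "annotated" and model.source == "annotated":
                continue
            if (
                model.start >= other.start - end_window
                and model.end <= other.end + end_window
            ):
                kind = "equal"
            else:
                continue
        else:
            kind = _is_strict_terminal_subchain(
                model.junctions(), other.junctions()
            )
            if kind is None:
                continue
            if kind == "suffix":
                if abs(model.end - other.end) > end_window:
                    continue
                if model.start < other.start - end_window:
                    continue
            else:
                if abs(model.start - other.start) > end_window:
                    continue
                if model.end > other.end + end_window:
                    continue
        key = (-len(other_reads), other.transcript_id)
        if best is None or key < best[0]:
            best = (key, (other, other_reads))
    return best[1] if best is not None else None
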