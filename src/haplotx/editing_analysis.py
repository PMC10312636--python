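"""Long-read A-to-I editing analyses.

Inosine is read as guanosine by sequencers, so edits appear as A→G
mismatches on plus-strand genes and T→C on minus-strand genes.  All
analyses here are strand-aware via the host gene's annotation; positions
with no resolvable gene strand are skipped.

Provided analyses:

* strand-aware pileup of candidate edit positions per condition;
* two-condition differential editing (coverage, delta and Fisher filters);
* type I hyperediting (a single base with >40% of reads edited) and
  type II hyperediting (≥3 edits within every 150 bp of a region);
* per-read editing summaries;
* single-molecule coordination tests — edit–edit co-occurrence between
  nearby sites, and edit–intron mutual exclusivity, both within single
  reads.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import ReadAlignment
from .stats_core import ContingencyTable2x2, bh_adjust, fisher_exact_two_sided

logger = logging.getLogger(__name__)

_EDIT_BASE = {"+": ("A", "G"), "-": ("T", "C")}


@dataclass
class EditSite:
    """A strand-resolved candidate edit position with per-condition counts.

    ``counts`` maps condition name → (ref_reads, edit_reads); reads
    carrying other bases or deletions are excluded from the fraction
    denominator but tracked in ``other_counts``.
    """

    chrom: str
    pos0: int
    gene_strand: str
    known: bool = False
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    other_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ref_base(self) -> str:
        return _EDIT_BASE[self.gene_strand][0]

    @property
    def edit_base(self) -> str:
        return _EDIT_BASE[self.gene_strand][1]

    def coverage(self, condition: str) -> int:
        ref, edit = self.counts.get(condition, (0, 0))
        return ref + edit

    def edit_fraction(self, condition: str) -> float:
        ref, edit = self.counts.get(condition, (0, 0))
        if ref + edit == 0:
            raise ValueError(f"uncovered site {self.chrom}:{self.pos0}")
        return edit / (ref + edit)


def classify_read_at_site(
    read: ReadAlignment, pos0: int, gene_strand: str
) -> str:
    """Classify one read at one candidate site.

    Returns "ref", "edit", "other", "spliced_out" (position inside one of
    the read's intron ops), or "uncovered".
    """
    state = read.op_state_at(pos0)
    if state == "intron":
        return "spliced_out"
    if state in ("uncovered", "deletion"):
        return "uncovered" if state == "uncovered" else "other"
    ref_base, edit_base = _EDIT_BASE[gene_strand]
    if state == "match":
        return "ref"
    base = read.base_at(pos0)
    if base == edit_base:
        return "edit"
    return "other"


def pileup_edit_counts(
    condition_reads: Mapping[str, Sequence[ReadAlignment]],
    candidate_positions: Sequence[tuple[str, int]],
    gene_strands: Mapping[tuple[str, int], str],
    known_sites: set[tuple[str, int]] | None = None,
) -> list[EditSite]:
    """Count strand-appropriate reference vs edited reads per site and
    condition.

    ``gene_strands`` maps (chrom, pos0) → host-gene strand; positions with
    no entry are skipped with a log message.  Counts are independent of
    read order.
    """
    known_sites = known_sites or set()
    sites: list[EditSite] = []
    reads_by_chrom: dict[str, dict[str, list[ReadAlignment]]] = defaultdict(dict)
    for cond, reads in condition_reads.items():
        by_chrom: dict[str, list[ReadAlignment]] = defaultdict(list)
        for read in reads:
            if read.blocks:
                by_chrom[read.blocks[0].chrom].append(read)
        for chrom, lst in by_chrom.items():
            reads_by_chrom[chrom][cond] = lst
    for chrom, pos0 in sorted(set(candidate_positions)):
        strand = gene_strands.get((chrom, pos0))
        if strand is None:
            logger.info("skipping %s:%d — no resolvable gene strand", chrom, pos0)
            continue
        site = EditSite(chrom, pos0, strand, known=(chrom, pos0) in known_sites)
        for cond in sorted(condition_reads):
            ref = edit = other = 0
            for read in reads_by_chrom.get(chrom, {}).get(cond, []):
                call = classify_read_at_site(read, pos0, strand)
                if call == "ref":
                    ref += 1
                elif call == "edit":
                    edit += 1
                elif call == "other":
                    other += 1
            site.counts[cond] = (ref, edit)
            site.other_counts[cond] = other
        sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# Differential editing
# ---------------------------------------------------------------------------


@dataclass
class DifferentialEditResult:
    site: EditSite
    fraction_control: float
    fraction_knockdown: float
    delta: float  # control − knockdown
    p: float
    direction: str  # "down" if knockdown fraction < control fraction
    type1_in_control: bool
    p_adj: float = 1.0


def differential_editing(
    sites: Sequence[EditSite],
    control: str,
    knockdown: str,
    min_cov: int = 10,
    min_delta: float = 0.10,
    alpha: float = 0.05,
    type1_threshold: float = 0.40,
) -> list[DifferentialEditResult]:
    """Two-condition differential editing with the long-read filters.

    A site is retained when the larger of its two coverages is ≥
    ``min_cov`` ("minimum coverage in either condition"), the edit-fraction
    change is ≥ ``min_delta``, and the Fisher's exact p on
    [[edit₁, ref₁], [edit₂, ref₂]] is < ``alpha``.  Replicates are assumed
    pooled per condition upstream.
    """
    results = []
    for site in sites:
        cov_c, cov_k = site.coverage(control), site.coverage(knockdown)
        if max(cov_c, cov_k) < min_cov or min(cov_c, cov_k) == 0:
            continue
        frac_c = site.edit_fraction(control)
        frac_k = site.edit_fraction(knockdown)
        if abs(frac_c - frac_k) < min_delta:
            continue
        ref_c, edit_c = site.counts[control]
        ref_k, edit_k = site.counts[knockdown]
        p = fisher_exact_two_sided(
            ContingencyTable2x2(edit_c, ref_c, edit_k, ref_k)
        )
        if p >= alpha:
            continue
        results.append(
            DifferentialEditResult(
                site=site,
                fraction_control=frac_c,
                fraction_knockdown=frac_k,
                delta=frac_c - frac_k,
                p=p,
                direction="down" if frac_k < frac_c else "up",
                type1_in_control=frac_c > type1_threshold,
            )
        )
    if results:
        adjusted = bh_adjust([r.p for r in results])
        for r, padj in zip(results, adjusted):
            r.p_adj = padj
    return results


# ---------------------------------------------------------------------------
# Hyperediting
# ---------------------------------------------------------------------------


def classify_type1(
    site: EditSite, condition: str, threshold: float = 0.40
) -> bool:
    """Type I hyperediting: strictly more than ``threshold`` of covering
    reads are edited.  Raises on an uncovered site."""
    return site.edit_fraction(condition) > threshold


@dataclass
class HypereditedRegion:
    chrom: str
    start: int
    end: int  # half-open: max member position + 1
    positions: tuple[int, ...]

    @property
    def n_edits(self) -> int:
        return len(self.positions)


def detect_type2_regions(
    positions: Sequence[int],
    chrom: str = ".",
    window: int = 150,
    min_edits: int = 3,
) -> list[HypereditedRegion]:
    """Maximal clusters of edits with ≥``min_edits`` inside every
    ``window`` bp.

    A run of ``min_edits`` consecutive positions spanning < ``window`` bp
    qualifies; overlapping qualifying runs merge into maximal regions whose
    bounds are their outermost member positions.
    """
    pos = sorted(set(positions))
    n = len(pos)
    regions: list[HypereditedRegion] = []
    if n < min_edits:
        return regions
    qualifying = [
        i for i in range(n - min_edits + 1) if pos[i + min_edits - 1] - pos[i] < window
    ]
    if not qualifying:
        return regions
    run_start = qualifying[0]
    prev = qualifying[0]
    spans: list[tuple[int, int]] = []
    for i in qualifying[1:]:
        if i <= prev + min_edits - 1:  # windows share a member edit
            prev = i
        else:
            spans.append((run_start, prev + min_edits - 1))
            run_start = prev = i
    spans.append((run_start, prev + min_edits - 1))
    for lo, hi in spans:
        members = tuple(pos[lo : hi + 1])
        regions.append(
            HypereditedRegion(chrom, members[0], members[-1] + 1, members)
        )
    return regions


def summarize_read_editing(
    reads: Sequence[ReadAlignment],
    sites: Sequence[EditSite],
) -> tuple[float, float, int]:
    """Per-read editing summary over reads overlapping ≥1 candidate site.

    Returns (fraction of overlapping reads with ≥1 edit, fraction of edited
    reads with ≥2 edits, number of overlapping reads).  With zero edited
    reads the second fraction is reported as 0.
    """
    by_chrom: dict[str, list[EditSite]] = defaultdict(list)
    for site in sites:
        by_chrom[site.chrom].append(site)
    n_overlapping = n_edited = n_multi = 0
    for read in reads:
        if not read.blocks:
            continue
        chrom = read.blocks[0].chrom
        edits = covered = 0
        for site in by_chrom.get(chrom, []):
            call = classify_read_at_site(read, site.pos0, site.gene_strand)
            if call in ("ref", "edit", "other"):
                covered += 1
                if call == "edit":
                    edits += 1
        if covered == 0:
            continue
        n_overlapping += 1
        if edits >= 1:
            n_edited += 1
        if edits >= 2:
            n_multi += 1
    if n_overlapping == 0:
        return 0.0, 0.0, 0
    frac_edited = n_edited / n_overlapping
    frac_multi = n_multi / n_edited if n_edited else 0.0
    return frac_edited, frac_multi, n_overlapping


# ---------------------------------------------------------------------------
# Single-molecule coordination
# ---------------------------------------------------------------------------


@dataclass
class CoordinationResult:
    site_a: EditSite
    site_b: EditSite
    table: ContingencyTable2x2  # (both, only A, only B, neither)
    p: float
    p_adj: float = 1.0

    @property
    def distance(self) -> int:
        return abs(self.site_b.pos0 - self.site_a.pos0)


def edit_edit_coordination(
    sites: Sequence[EditSite],
    reads: Sequence[ReadAlignment],
    k_nearest: int = 20,
    min_distance: int = 50,
    alpha: float = 0.05,
) -> list[CoordinationResult]:
    """Test co-occurrence of edits at nearby site pairs within single reads.

    For each site, its ``k_nearest`` candidate neighbours (by genomic
    distance, both directions, same chromosome) at ≥ ``min_distance`` bp
    are paired; each unordered pair is tested once.  Per pair, reads
    covering both sites exonically fill the 2×2 (both edited / only A /
    only B / neither); pairs with Fisher p < ``alpha`` are reported with a
    BH-adjusted column (significance is judged on the raw p).
    """
    by_chrom: dict[str, list[EditSite]] = defaultdict(list)
    for site in sites:
        by_chrom[site.chrom].append(site)
    reads_by_chrom: dict[str, list[ReadAlignment]] = defaultdict(list)
    for read in reads:
        if read.blocks:
            reads_by_chrom[read.blocks[0].chrom].append(read)

    pairs: set[tuple[int, int]] = set()
    site_index: dict[int, EditSite] = {}
    for chrom, chrom_sites in by_chrom.items():
        chrom_sites.sort(key=lambda s: s.pos0)
        for i, site in enumerate(chrom_sites):
            site_index[id(site)] = site
            neighbours = sorted(
                (s for j, s in enumerate(chrom_sites) if j != i),
                key=lambda s: (abs(s.pos0 - site.pos0), s.pos0),
            )
            for other in neighbours[:k_nearest]:
                if abs(other.pos0 - site.pos0) < min_distance:
                    continue
                pairs.add(
                    (min(id(site), id(other)), max(id(site), id(other)))
                )

    results: list[CoordinationResult] = []
    tested: list[CoordinationResult] = []
    for ia, ib in sorted(
        pairs, key=lambda t: (site_index[t[0]].chrom, site_index[t[0]].pos0, site_index[t[1]].pos0)
    ):
        a, b = site_index[ia], site_index[ib]
        if a.pos0 > b.pos0:
            a, b = b, a
        both = only_a = only_b = neither = 0
        for read in reads_by_chrom.get(a.chrom, []):
            ca = classify_read_at_site(read, a.pos0, a.gene_strand)
            cb = classify_read_at_site(read, b.pos0, b.gene_strand)
            if ca not in ("ref", "edit") or cb not in ("ref", "edit"):
                continue
            if ca == "edit" and cb == "edit":
                both += 1
            elif ca == "edit":
                only_a += 1
            elif cb == "edit":
                only_b += 1
            else:
                neither += 1
        if both + only_a + only_b + neither < 1:
            continue
        table = ContingencyTable2x2(both, only_a, only_b, neither)
        tested.append(
            CoordinationResult(a, b, table, fisher_exact_two_sided(table))
        )
    if tested:
        adjusted = bh_adjust([r.p for r in tested])
        for r, padj in zip(tested, adjusted):
            r.p_adj = padj
    results = [r for r in tested if r.p < alpha]
    return results


@dataclass
class EditIntronSite:
    site: EditSite
    n_edited: int
    n_ref: int
    n_spliced: int

    @property
    def edit_fraction(self) -> float:
        return self.n_edited / (self.n_edited + self.n_ref)


def edit_intron_coordination(
    sites: Sequence[EditSite],
    reads: Sequence[ReadAlignment],
    condition_filter=None,
    type1_threshold: float = 0.40,
    min_edited_reads: int = 10,
    min_spliced_reads: int = 10,
) -> list[EditIntronSite]:
    """Sites where editing and splicing-out are mutually exclusive states.

    A site is reported when, among reads covering it exonically, its edit
    fraction exceeds ``type1_threshold`` (type I hyperedited), at least
    ``min_edited_reads`` reads are edited, and at least
    ``min_spliced_reads`` reads carry the position inside a spliced-out
    intron.
    """
    reads_by_chrom: dict[str, list[ReadAlignment]] = defaultdict(list)
    for read in reads:
        if read.blocks:
            reads_by_chrom[read.blocks[0].chrom].append(read)
    out: list[EditIntronSite] = []
    for site in sites:
        n_ref = n_edit = n_spliced = 0
        for read in reads_by_chrom.get(site.chrom, []):
            call = classify_read_at_site(read, site.pos0, site.gene_strand)
            if call == "ref":
                n_ref += 1
            elif call == "edit":
                n_edit += 1
            elif call == "spliced_out":
                n_spliced += 1
        if n_ref + n_edit == 0:
            continue
        fraction = n_edit / (n_ref + n_edit)
        if (
            fraction > type1_threshold
            and n_edit >= min_edited_reads
            and n_spliced >= min_spliced_reads
        ):
            out.append(EditIntronSite(site, n_edit, n_ref, n_spliced))
    return out
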