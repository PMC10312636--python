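"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from math import comb

import pytest

from haplotx.io_formats import AlnOp, GenomeInterval, ReadAlignment, TranscriptModel


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p: enumerate every table with the same
    margins and sum hypergeometric probabilities ≤ the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def type2_oracle(positions, window: int = 150, min_edits: int = 3):
    """Enumerate every window anchored at an edit; merge windows sharing a
    member edit; report (start, end, members) per merged region."""
    pos = sorted(set(positions))
    windows = []
    for p in pos:
        members = tuple(q for q in pos if p <= q < p + window)
        if len(members) >= min_edits:
            windows.append(set(members))
    regions = []
    current: set | None = None
    for w in windows:
        if current is not None and current & w:
            current |= w
        else:
            if current is not None:
                regions.append(current)
            current = set(w)
    if current is not None:
        regions.append(current)
    return [
        (min(r), max(r) + 1, tuple(sorted(r))) for r in regions
    ]


# ---------------------------------------------------------------------------
# Alignment construction helpers
# ---------------------------------------------------------------------------


def make_aln(
    segments,
    start: int = 0,
    chrom: str = "tx",
    target_kind: str = "transcript",
    read_id: str = "r1",
    mapq: int = 60,
    strand: str = "+",
) -> ReadAlignment:
    """Build a ReadAlignment from (kind, length[, bases]) tuples.

    Target position advances through match/mismatch/deletion/intron ops;
    intron ops split blocks (genome targets only).
    """
    ops = []
    blocks = []
    pos = start
    block_start = start
    for seg in segments:
        kind, length = seg[0], seg[1]
        bases = seg[2] if len(seg) > 2 else ("N" * length if kind in ("mismatch", "insertion") else None)
        if kind == "insertion":
            ops.append(AlnOp(kind, length, pos, bases))
            continue
        if kind == "intron":
            if pos > block_start:
                blocks.append(GenomeInterval(chrom, block_start, pos, strand))
            ops.append(AlnOp(kind, length, pos))
            pos += length
            block_start = pos
            continue
        ops.append(AlnOp(kind, length, pos, bases))
        pos += length
    if pos > block_start:
        blocks.append(GenomeInterval(chrom, block_start, pos, strand))
    return ReadAlignment(
        read_id=read_id,
        target_id=chrom,
        target_kind=target_kind,
        blocks=blocks,
        ops=ops,
        mapq=mapq,
        strand=strand,
    )


def single_exon_transcript(
    length: int = 100, tid: str = "tx", chrom: str = "chr1", strand: str = "+"
) -> TranscriptModel:
    return TranscriptModel(
        tid, "g", [GenomeInterval(chrom, 0, length, strand)], "annotated"
    )


@pytest.fixture
def two_exon_transcript() -> TranscriptModel:
    """Plus-strand transcript: exons [100,400) and [700,1000), junction at
    transcript offset 300, length 600."""
    return TranscriptModel(
        "tx2",
        "g1",
        [
            GenomeInterval("chr1", 100, 400, "+"),
            GenomeInterval("chr1", 700, 1000, "+"),
        ],
        "annotated",
    )
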