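"""Transcript-set comparison for benchmarking isoform detection.

A predicted transcript matches a ground-truth transcript when their
junction chains are identical at exact coordinates and both terminal ends
agree within a wiggle (50 bp by default, mirroring common spike-in
benchmarking practice).  Matching is greedy 1-to-1 by smallest total end
distance, so each truth transcript is claimed at most once; transcript-level
sensitivity and precision follow from the matched counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import TranscriptModel


@dataclass
class MatchReport:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        """Percent of truth transcripts recovered: 100·tp/(tp+fn)."""
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def precision(self) -> float:
        """Percent of predictions that are real: 100·tp/(tp+fp)."""
        return 100.0 * self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0


def _compatible(
    pred: TranscriptModel, truth: TranscriptModel, end_wiggle: int
) -> int | None:
    """Total end distance when the pair matches under the wiggle rule,
    else None.

    Multi-exon: identical junction chain (exact internal coordinates) and
    |TSS difference| ≤ wiggle and |TES difference| ≤ wiggle.  Mono-exon:
    both mono-exon, overlapping, both ends within the wiggle.
    """
    if pred.chrom != truth.chrom:
        return None
    if pred.junctions() != truth.junctions():
        return None
    d_start = abs(pred.start - truth.start)
    d_end = abs(pred.end - truth.end)
    if d_start > end_wiggle or d_end > end_wiggle:
        return None
    if not pred.junctions():
        if not (pred.start < truth.end and truth.start < pred.end):
            return None
    return d_start + d_end


def match_transcripts(
    predicted: Sequence[TranscriptModel],
    truth: Sequence[TranscriptModel],
    end_wiggle: int = 50,
) -> MatchReport:
    """Greedy 1-to-1 matching of predicted to truth transcripts.

    Candidate pairs are ranked by total end distance (ties broken by
    predicted then truth transcript id) and claimed greedily, so the
    assignment is deterministic and each transcript on either side matches
    at most once.
    """
    candidates: list[tuple[int, str, str, int, int]] = []
    for i, pred in enumerate(predicted):
        for j, tru in enumerate(truth):
            dist = _compatible(pred, tru, end_wiggle)
            if dist is not None:
                candidates.append(
                    (dist, pred.transcript_id, tru.transcript_id, i, j)
                )
    candidates.sort()
    used_pred: set[int] = set()
    used_truth: set[int] = set()
    pairs: list[tuple[str, str]] = []
    for _dist, pred_id, truth_id, i, j in candidates:
        if i in used_pred or j in used_truth:
            continue
        used_pred.add(i)
        used_truth.add(j)
        pairs.append((pred_id, truth_id))
    tp = len(pairs)
    return MatchReport(
        tp=tp,
        fp=len(predicted) - tp,
        fn=len(truth) - tp,
        pairs=sorted(pairs),
    )
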