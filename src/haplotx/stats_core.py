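"""Statistical primitives used throughout the pipeline.

Two operations: the two-sided Fisher's exact test on 2×2 contingency
tables, and multiple-testing adjustment (Benjamini–Hochberg by default,
Bonferroni as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) / (c, d): rows = groups, columns = outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_two_sided(table: ContingencyTable2x2 | tuple) -> float:
    """Two-sided Fisher's exact p-value for a 2×2 table.

    Uses the standard "sum of all tables with the same margins whose
    hypergeometric probability is ≤ that of the observed table" convention
    (ties included up to a small relative tolerance).  A table with an empty
    row or column margin carries no information and returns p = 1.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    if table.n == 0:
        raise ValueError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        logger.debug("empty margin in table %s; p=1", table)
        return 1.0
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def bh_adjust(pvalues, method: str = "bh") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    method="bh" applies the Benjamini–Hochberg step-up procedure:
    adjusted_i = min_{j : p_j >= p_i} (p_j * m / rank_j), capped at 1, so the
    output is monotone in the input.  method="bonferroni" multiplies by m.
    Inputs outside [0, 1] are hard errors.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return list(np.minimum(p * m, 1.0))
    if method != "bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return list(adjusted)
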