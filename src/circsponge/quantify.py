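"""Back-splice-junction read counting and RPM expression.

A circRNA is observed only through reads spanning its back-splice junction.
Expression is reported as RPM = 1e6 * C / N, where C is the number of
back-spliced reads assigned to the circRNA in a sample and N is the total
number of back-spliced reads assigned to all circRNAs in that sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("circsponge")


@dataclass(frozen=True)
class CircRecord:
    """A circRNA as a back-splice junction on a genome.

    ``junction_seq`` is the junction-spanning sequence in spliced order:
    k bases upstream of the donor (circle 3' end) followed by k bases
    downstream of the acceptor (circle 5' start), so the back-splice seam
    sits at the midpoint.
    """

    circ_id: str
    chrom: str
    start: int  # 0-based, junction acceptor
    end: int  # half-open, junction donor
    strand: str
    junction_seq: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.circ_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.circ_id}: strand must be '+' or '-'")
        if self.junction_seq:
            n = len(self.junction_seq)
            if n % 2 != 0 or n < 20:
                raise ValueError(
                    f"{self.circ_id}: junction_seq length must be even and >= 20 (2k, k >= 10)"
                )

    @property
    def half_length(self) -> int:
        return len(self.junction_seq) // 2


def _overlap_hit(read: str, junction: str, k: int, min_overhang: int, max_mismatches: int) -> bool:
    """True if some alignment offset of ``read`` against ``junction`` covers the
    seam midpoint by >= min_overhang on each side with <= max_mismatches."""
    lr = len(read)
    lo = k + min_overhang - lr  # smallest read offset still covering the seam
    hi = k - min_overhang  # largest read offset still covering the seam
    for o in range(max(lo, -(lr - 1)), min(hi, 2 * k - 1) + 1):
        a = max(0, o)
        b = min(2 * k, o + lr)
        if a > k - min_overhang or b < k + min_overhang:
            continue
        mism = sum(1 for i in range(a, b) if junction[i] != read[i - o])
        if mism <= max_mismatches:
            return True
    return False


def count_junction_reads(
    reads: Sequence[str],
    circs: Sequence[CircRecord],
    min_overhang: int = 5,
    max_mismatches: int = 1,
) -> np.ndarray:
    """Count back-splice junction-spanning reads for one sample.

    A read increments the count of a circRNA if it aligns to the circRNA's
    junction-spanning sequence with at most ``max_mismatches`` mismatches in
    the overlap and at least ``min_overhang`` aligned bases on each side of
    the junction seam.  A read counts at most once per circRNA; a read
    matching several circRNAs increments each of them.
    """
    if not circs:
        raise ValueError("empty circRNA list")
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    counts = np.zeros(len(circs), dtype=int)
    reads = [r.upper() for r in reads]
    for ci, circ in enumerate(circs):
        if not circ.junction_seq:
            raise ValueError(f"{circ.circ_id}: no junction sequence available for counting")
        k = circ.half_length
        if k < min_overhang:
            raise ValueError(f"{circ.circ_id}: junction half-length {k} < min_overhang")
        junction = circ.junction_seq.upper()
        for read in reads:
            if max_mismatches == 0 and len(read) >= 2 * k:
                if junction in read:
                    counts[ci] += 1
                continue
            if _overlap_hit(read, junction, k, min_overhang, max_mismatches):
                counts[ci] += 1
    return counts


def _validate_counts(counts: pd.DataFrame) -> None:
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")


def rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """RPM_ij = 1e6 * C_ij / N_j with N_j the column total of back-spliced reads.

    Columns with N_j = 0 are returned as all-zero with a logged warning.
    """
    _validate_counts(counts)
    totals = counts.sum(axis=0).astype(float)
    zero_cols = totals.index[totals == 0]
    for col in zero_cols:
        log.warning("sample %s has zero back-spliced reads; RPM column set to 0", col)
    safe = totals.replace(0.0, np.nan)
    out = counts.astype(float).div(safe, axis=1) * 1e6
    return out.fillna(0.0)


def group_mean_rpm(
    rpm_matrix: pd.DataFrame, groups: Mapping[str, str], group: str
) -> pd.Series:
    """Arithmetic mean RPM across the replicates of one group, per circRNA."""
    samples = [s for s in rpm_matrix.columns if groups.get(s) == group]
    if not samples:
        raise KeyError(f"unknown or empty group {group!r}")
    return rpm_matrix[samples].mean(axis=1)


def group_sum_counts(
    counts: pd.DataFrame, groups: Mapping[str, str], group: str
) -> pd.Series:
    """Pooled junction-read counts across the replicates of one group."""
    samples = [s for s in counts.columns if groups.get(s) == group]
    if not samples:
        raise KeyError(f"unknown or empty group {group!r}")
    return counts[samples].sum(axis=1)
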