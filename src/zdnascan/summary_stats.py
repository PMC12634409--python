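"""Per-sequence and pooled ZFS statistics.

One :class:`SummaryStats` row per scanned sequence: hit count, summed
bp, median and maximum hit length, frequency per 1000 bp and percent
coverage, plus the sequence's G+C content when the residues are
available.  ``aggregate`` pools rows into a TOTAL row, recomputing
frequency and coverage from the pooled totals rather than averaging.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .detector import ZfsHit

__all__ = ["SummaryStats", "summarize", "filter_long", "aggregate",
           "write_stats_csv", "LONG_ZFS_MIN_BP"]

#: Two Z-DNA helical turns' worth of the 12-bp minimum.
LONG_ZFS_MIN_BP = 24


@dataclass(frozen=True)
class SummaryStats:
    sequence_id: str
    seq_length: int
    zfs_count: int
    zfs_total_bp: int
    zfs_median_length: float
    zfs_max_length: int
    zfs_freq_per_kb: float
    zfs_coverage_percent: float
    gc_content: float | None = None
    #: retained hit lengths; lets aggregate() recompute a pooled median
    hit_lengths: tuple[int, ...] = field(default=(), repr=False)
    #: (G+C count, ACGT count) for pooled G+C recomputation
    base_counts: tuple[int, int] | None = field(default=None, repr=False)


def _gc_base_counts(sequence: str) -> tuple[int, int]:
    """(G+C, total ACGT) ignoring N/ambiguity codes and gaps."""
    up = sequence.upper()
    gc = up.count("G") + up.count("C")
    acgt = gc + up.count("A") + up.count("T")
    return gc, acgt


def summarize(hits: Sequence[ZfsHit], seq_length: int,
              sequence: str | None = None,
              sequence_id: str | None = None) -> SummaryStats:
    """Statistics for one sequence's hits.

    With zero hits the median and max are reported as 0.  G+C content
    is computed only when *sequence* is supplied, over ACGT bases
    (assembly-gap Ns are excluded from the denominator).
    """
    ids = {h.sequence_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple sequences: {sorted(ids)}")
    if sequence_id is None:
        sequence_id = ids.pop() if ids else "seq1"
    if hits and max(h.end for h in hits) > seq_length:
        raise ValueError("hit end exceeds sequence length")
    if sequence is not None and len(sequence) != seq_length:
        raise ValueError("sequence length disagrees with seq_length")

    lengths = tuple(h.length for h in hits)
    total_bp = sum(lengths)
    gc = base_counts = None
    if sequence is not None:
        base_counts = _gc_base_counts(sequence)
        gc = 100.0 * base_counts[0] / base_counts[1] if base_counts[1] else 0.0
    return SummaryStats(
        sequence_id=sequence_id,
        seq_length=seq_length,
        zfs_count=len(lengths),
        zfs_total_bp=total_bp,
        zfs_median_length=float(statistics.median(lengths)) if lengths else 0.0,
        zfs_max_length=max(lengths) if lengths else 0,
        zfs_freq_per_kb=1000.0 * len(lengths) / seq_length if seq_length else 0.0,
        zfs_coverage_percent=100.0 * total_bp / seq_length if seq_length else 0.0,
        gc_content=gc,
        hit_lengths=tuple(sorted(lengths)),
        base_counts=base_counts,
    )


def filter_long(hits: Iterable[ZfsHit],
                min_long: int = LONG_ZFS_MIN_BP) -> list[ZfsHit]:
    """Keep hits of length >= *min_long* bp (inclusive), order preserved."""
    return [h for h in hits if h.length >= min_long]


def aggregate(per_seq: Sequence[SummaryStats],
              sequence_id: str = "TOTAL") -> SummaryStats:
    """Pool per-sequence rows: counts and bp are summed; frequency and
    coverage are recomputed from the pooled totals (never averaged).

    The pooled median is recomputed over the concatenated hit-length
    multiset when every row retained its lengths, else reported as
    NaN; likewise pooled G+C needs every row's base counts.
    """
    if not per_seq:
        raise ValueError("aggregate requires at least one row")
    ids = [s.sequence_id for s in per_seq]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence_id in aggregation input")

    total_len = sum(s.seq_length for s in per_seq)
    count = sum(s.zfs_count for s in per_seq)
    total_bp = sum(s.zfs_total_bp for s in per_seq)

    have_lengths = all(len(s.hit_lengths) == s.zfs_count for s in per_seq)
    pooled = sorted(l for s in per_seq for l in s.hit_lengths) if have_lengths else None
    if pooled is not None:
        median = float(statistics.median(pooled)) if pooled else 0.0
        max_len = max(pooled) if pooled else 0
    else:
        median = float("nan")
        max_len = max(s.zfs_max_length for s in per_seq)

    gc = base = None
    if all(s.base_counts is not None for s in per_seq):
        g = sum(s.base_counts[0] for s in per_seq)
        n = sum(s.base_counts[1] for s in per_seq)
        base = (g, n)
        gc = 100.0 * g / n if n else 0.0

    return SummaryStats(
        sequence_id=sequence_id,
        seq_length=total_len,
        zfs_count=count,
        zfs_total_bp=total_bp,
        zfs_median_length=median,
        zfs_max_length=max_len,
        zfs_freq_per_kb=1000.0 * count / total_len if total_len else 0.0,
        zfs_coverage_percent=100.0 * total_bp / total_len if total_len else 0.0,
        gc_content=gc,
        hit_lengths=tuple(pooled) if pooled is not None else (),
        base_counts=base,
    )


_STATS_COLUMNS = [
    "sequence_id", "seq_length", "gc_content", "zfs_count", "zfs_total_bp",
    "zfs_median_length", "zfs_max_length", "zfs_freq_per_kb",
    "zfs_coverage_percent",
]


def write_stats_csv(per_seq: Sequence[SummaryStats], path,
                    total_row: bool = True) -> None:
    """One CSV row per sequence plus a TOTAL row."""
    rows = list(per_seq)
    if total_row and rows:
        rows.append(aggregate(rows))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_STATS_COLUMNS)
        for s in rows:
            writer.writerow([
                s.sequence_id, s.seq_length,
                "" if s.gc_content is None else f"{s.gc_content:.2f}",
                s.zfs_count, s.zfs_total_bp,
                f"{s.zfs_median_length:.1f}", s.zfs_max_length,
                f"{s.zfs_freq_per_kb:.3f}", f"{s.zfs_coverage_percent:.3f}",
            ])
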