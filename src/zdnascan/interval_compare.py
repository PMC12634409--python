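"""Interval algebra for benchmarking and genomic-context analysis.

Everything here operates on 0-based half-open intervals (BED
convention).  The core operations are:

* :func:`match_rate` — sensitivity / false-positive rate under the
  ">= 1 bp overlap" match rule used for benchmarking predictions
  against validated reference sets;
* :func:`venn_bp` — decomposition of 2 or 3 merged interval sets into
  exclusive regions with bp totals (Venn-style overlap accounting);
* :func:`density_per_kb` — hit density within genomic compartments
  (e.g. euchromatin vs heterochromatin), midpoint rule by default;
* :func:`expected_random_overlaps` — overlaps expected if hits were
  placed uniformly at random over the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = ["IntervalSet", "MatchResult", "match_rate", "venn_bp",
           "density_per_kb", "expected_random_overlaps", "promoter_windows"]


@dataclass
class IntervalSet:
    """Per-chrom interval lists, 0-based half-open, with a label."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            for start, end in ivs:
                if start >= end:
                    raise ValueError(
                        f"{chrom}: invalid interval [{start}, {end})")
            self.intervals[chrom] = sorted(ivs)

    @classmethod
    def from_bed(cls, path, label: str = "") -> "IntervalSet":
        from .sequence_io import read_bed

        return cls(read_bed(path), label=label or str(path))

    @classmethod
    def from_hits(cls, hits: Iterable, label: str = "") -> "IntervalSet":
        ivs: dict[str, list[tuple[int, int]]] = {}
        for h in hits:
            ivs.setdefault(h.sequence_id, []).append((h.start, h.end))
        return cls(ivs, label=label)

    def merged(self) -> "IntervalSet":
        """Union of this set as disjoint sorted intervals."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in self.intervals.items():
            merged: list[tuple[int, int]] = []
            for start, end in sorted(ivs):
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            out[chrom] = merged
        return IntervalSet(out, label=self.label)

    def total_bp(self) -> int:
        m = self.merged()
        return sum(e - s for ivs in m.intervals.values() for s, e in ivs)

    def count(self) -> int:
        return sum(len(ivs) for ivs in self.intervals.values())

    def chroms(self) -> list[str]:
        return sorted(self.intervals)


@dataclass(frozen=True)
class MatchResult:
    sensitivity: float          # % of reference intervals hit by >= 1 bp
    false_positive_rate: float  # % of predicted intervals hitting nothing
    matched: int                # matched reference intervals
    unmatched_pred: int
    unmatched_ref: int


def _trees(iset: IntervalSet) -> dict[str, IntervalTree]:
    return {chrom: IntervalTree.from_tuples(ivs)
            for chrom, ivs in iset.intervals.items() if ivs}


def match_rate(predicted: IntervalSet, reference: IntervalSet) -> MatchResult:
    """Benchmark *predicted* against *reference* with the >= 1 bp rule.

    A reference interval is matched when any predicted interval
    overlaps it by at least 1 bp (half-open adjacency is not overlap).
    Chromosomes present in only one set count as unmatched.
    """
    only_pred = set(predicted.intervals) - set(reference.intervals)
    only_ref = set(reference.intervals) - set(predicted.intervals)
    for chrom in sorted(only_pred | only_ref):
        log.warning("chromosome %s present in only one interval set", chrom)

    pred_trees = _trees(predicted)
    ref_trees = _trees(reference)

    n_ref = reference.count()
    n_pred = predicted.count()
    matched_ref = sum(
        1 for chrom, ivs in reference.intervals.items()
        for s, e in ivs if chrom in pred_trees and pred_trees[chrom].overlap(s, e)
    )
    matched_pred = sum(
        1 for chrom, ivs in predicted.intervals.items()
        for s, e in ivs if chrom in ref_trees and ref_trees[chrom].overlap(s, e)
    )
    return MatchResult(
        sensitivity=100.0 * matched_ref / n_ref if n_ref else 0.0,
        false_positive_rate=(100.0 * (n_pred - matched_pred) / n_pred
                             if n_pred else 0.0),
        matched=matched_ref,
        unmatched_pred=n_pred - matched_pred,
        unmatched_ref=n_ref - matched_ref,
    )


def venn_bp(sets: Sequence[IntervalSet]) -> dict[str, int]:
    """bp totals of the exclusive regions of 2 or 3 interval sets.

    Each input is merged to disjoint intervals first, so overlaps
    within one set never double count.  Region labels join the set
    labels (or A/B/C) with ``&``; the values sum to bp(union).
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_bp supports exactly 2 or 3 interval sets")
    labels = [s.label or chr(ord("A") + i) for i, s in enumerate(sets)]
    if len(set(labels)) != len(labels):
        labels = [chr(ord("A") + i) for i in range(len(sets))]
    merged = [s.merged().intervals for s in sets]

    regions: dict[str, int] = {}
    for k in range(1, 2 ** len(sets)):
        name = "&".join(labels[i] for i in range(len(sets)) if k >> i & 1)
        regions[name] = 0

    chroms = set().union(*(m.keys() for m in merged))
    for chrom in chroms:
        # sweep over elementary segments between all boundary points
        points = sorted({p for m in merged for s, e in m.get(chrom, []) for p in (s, e)})
        membership = [m.get(chrom, []) for m in merged]
        idx = [0] * len(sets)
        for a, b in zip(points, points[1:]):
            mask = 0
            for i, ivs in enumerate(membership):
                while idx[i] < len(ivs) and ivs[idx[i]][1] <= a:
                    idx[i] += 1
                if idx[i] < len(ivs) and ivs[idx[i]][0] <= a and ivs[idx[i]][1] >= b:
                    mask |= 1 << i
            if mask:
                name = "&".join(labels[i] for i in range(len(sets)) if mask >> i & 1)
                regions[name] += b - a
    return regions


def density_per_kb(hits: IntervalSet, compartments: IntervalSet,
                   rule: str = "midpoint") -> float:
    """Hit density per 1000 bp of compartment sequence.

    *rule* selects how a hit is assigned to the compartment:
    ``midpoint`` (default) counts hits whose midpoint lies inside a
    compartment interval; ``overlap`` counts hits with >= 1 bp overlap.
    """
    if rule not in ("midpoint", "overlap"):
        raise ValueError("rule must be 'midpoint' or 'overlap'")
    comp = compartments.merged()
    comp_bp = comp.total_bp()
    if comp_bp == 0:
        raise ValueError("compartment set has zero bp: density undefined")
    trees = _trees(comp)
    n = 0
    for chrom, ivs in hits.intervals.items():
        tree = trees.get(chrom)
        if tree is None:
            continue
        for s, e in ivs:
            if rule == "midpoint":
                mid = (s + e) // 2
                if tree.overlap(mid, mid + 1):
                    n += 1
            elif tree.overlap(s, e):
                n += 1
    return 1000.0 * n / comp_bp


def expected_random_overlaps(n_hits: int, feature_fraction: float) -> float:
    """Overlaps expected under uniform random placement of *n_hits*
    over a genome in which the feature occupies *feature_fraction*."""
    if not 0.0 <= feature_fraction <= 1.0:
        raise ValueError("feature_fraction must lie in [0, 1]")
    return n_hits * feature_fraction


def promoter_windows(tss: Iterable[tuple[str, int, str]],
                     upstream: int = 499, downstream: int = 100,
                     label: str = "promoters") -> IntervalSet:
    """Helper recipe: promoter windows around transcription start sites.

    *tss* yields ``(chrom, position, strand)`` with a 0-based TSS
    position; the window spans *upstream* bp upstream through
    *downstream* bp downstream of the TSS, strand-aware.  This is a
    data-preparation convenience for externally supplied annotations,
    not a scanned output.
    """
    ivs: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos, strand in tss:
        if strand == "-":
            start, end = pos - downstream, pos + upstream + 1
        else:
            start, end = pos - upstream, pos + downstream + 1
        ivs.setdefault(chrom, []).append((max(0, start), end))
    return IntervalSet(ivs, label=label)
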