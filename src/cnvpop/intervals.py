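"""Interval algebra on genomic coordinates.

All internal coordinates are 0-based half-open ``[start, end)`` (BED
convention); lengths are therefore ``end - start`` with no off-by-one
ambiguity.  Human-readable reports use 1-based inclusive coordinates; the
two converters below are the only place the +1/-1 happens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "overlap_length",
    "overlap_fraction",
    "cluster_by_overlap",
    "IntervalCluster",
    "union_length",
    "read_bed",
    "write_bed",
    "to_one_based",
    "from_one_based",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # 1-based inclusive for humans
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def to_one_based(iv: GenomicInterval) -> tuple[str, int, int]:
    """Return ``(chrom, start1, end1)`` in 1-based inclusive coordinates."""
    return iv.chrom, iv.start + 1, iv.end


def from_one_based(chrom: str, start1: int, end1: int) -> GenomicInterval:
    """Build an interval from 1-based inclusive coordinates."""
    return GenomicInterval(chrom, start1 - 1, end1)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared base pairs between two intervals (0 if disjoint or trans)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, denominator: str = "smaller"
) -> float:
    """Overlap length divided by a chosen denominator length.

    ``denominator`` is one of ``smaller``/``shortest`` (the shorter of the
    two; these are synonyms), ``a`` or ``b``.
    """
    ov = overlap_length(a, b)
    if denominator in ("smaller", "shortest"):
        denom = min(a.length, b.length)
    elif denominator == "a":
        denom = a.length
    elif denominator == "b":
        denom = b.length
    else:
        raise ValueError(f"unknown denominator rule: {denominator!r}")
    return ov / denom


@dataclass(frozen=True)
class IntervalCluster:
    """A connected group of mutually overlapping intervals."""

    envelope: GenomicInterval
    members: tuple[GenomicInterval, ...]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_by_overlap(
    intervals: Sequence[GenomicInterval], min_overlap_bp: int = 1
) -> list[IntervalCluster]:
    """Partition intervals into transitive-overlap clusters.

    Two intervals are linked when they share the same chromosome and at
    least ``min_overlap_bp`` bases; the partition is the transitive closure
    of that relation.  Each cluster carries its envelope (the span from the
    minimum start to the maximum end of its members).  Output is sorted by
    (chrom, envelope start, envelope end) and is invariant under the input
    order.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    ivs = sorted(intervals)  # canonical order: (chrom, start, end)
    if not ivs:
        return []
    uf = _UnionFind(len(ivs))
    # sorted by start: j can only overlap i by >= k bases while
    # start_j <= end_i - k, so the inner scan terminates early
    for i, a in enumerate(ivs):
        for j in range(i + 1, len(ivs)):
            b = ivs[j]
            if b.chrom != a.chrom or b.start > a.end - min_overlap_bp:
                break
            if min(a.end, b.end) - b.start >= min_overlap_bp:
                uf.union(i, j)
    groups: dict[int, list[GenomicInterval]] = {}
    for i, iv in enumerate(ivs):
        groups.setdefault(uf.find(i), []).append(iv)
    clusters = [
        IntervalCluster(
            envelope=GenomicInterval(
                ms[0].chrom, min(m.start for m in ms), max(m.end for m in ms)
            ),
            members=tuple(ms),
        )
        for ms in groups.values()
    ]
    clusters.sort(key=lambda c: (c.envelope.chrom, c.envelope.start, c.envelope.end))
    return clusters


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered by the union of the intervals (no double count)."""
    total = 0
    for cl in cluster_by_overlap(list(intervals), min_overlap_bp=1):
        # envelope length minus internal gaps: merge members directly
        ms = sorted(cl.members, key=lambda m: m.start)
        cur_start, cur_end = ms[0].start, ms[0].end
        for m in ms[1:]:
            if m.start <= cur_end:
                cur_end = max(cur_end, m.end)
            else:
                total += cur_end - cur_start
                cur_start, cur_end = m.start, m.end
        total += cur_end - cur_start
    return total


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3+ (tab-separated, 0-based half-open); extra columns ignored."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(path: str, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
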