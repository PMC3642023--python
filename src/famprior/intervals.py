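"""Genomic interval algebra on 1-based inclusive coordinates.

All coordinates in this package are 1-based and inclusive on both ends, the
convention of most genotyping-array and CNV call tables: the interval
chr13:26048387-26099109 spans 50,723 bases.  BED input/output converts to and
from 0-based half-open coordinates at the boundary (see :mod:`famprior.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "interval_length",
    "intersect_region_sets",
    "subtract_region_sets",
    "summarize_region_set",
    "overlap_fraction",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contiguous genomic span, 1-based and inclusive at both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (end < start)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_length(iv: GenomicInterval) -> int:
    """Length in base pairs of a 1-based inclusive interval (end - start + 1)."""
    return iv.length


def normalize_chrom(name: str, prefix: str | None = None) -> str:
    """Normalize a chromosome name to use (or drop) the ``chr`` prefix.

    ``prefix="chr"`` forces names like ``1`` to ``chr1``; ``prefix=""`` strips
    an existing prefix; ``None`` leaves the name untouched.
    """
    if prefix is None:
        return name
    bare = name[3:] if name.lower().startswith("chr") else name
    return prefix + bare


class RegionSet:
    """An ordered set of non-overlapping genomic intervals.

    Intervals are merged on construction: overlapping or abutting intervals
    (``end + 1 == next start``) on the same chromosome collapse into one
    maximal run.  Supports intersection, subtraction, union, point and
    interval queries.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            merged: List[Tuple[int, int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._by_chrom[chrom] = merged

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_tuples(cls, tuples: Iterable[Tuple[str, int, int]]) -> "RegionSet":
        return cls(GenomicInterval(c, s, e) for c, s, e in tuples)

    # -- container protocol ---------------------------------------------------
    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._by_chrom):
            for s, e in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, s, e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return {c: v for c, v in self._by_chrom.items() if v} == {
            c: v for c, v in other._by_chrom.items() if v
        }

    def __bool__(self) -> bool:
        return any(self._by_chrom.values())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, bp = self.summary()
        return f"RegionSet({n} intervals, {bp} bp)"

    def chromosomes(self) -> List[str]:
        return sorted(c for c, v in self._by_chrom.items() if v)

    # -- queries --------------------------------------------------------------
    def contains_point(self, chrom: str, pos: int) -> bool:
        import bisect

        spans = self._by_chrom.get(chrom)
        if not spans:
            return False
        i = bisect.bisect_right(spans, (pos, float("inf"))) - 1
        return i >= 0 and spans[i][0] <= pos <= spans[i][1]

    def total_bp(self) -> int:
        return sum(e - s + 1 for v in self._by_chrom.values() for s, e in v)

    def summary(self) -> Tuple[int, int]:
        """(number of intervals, total base pairs covered)."""
        return len(self), self.total_bp()

    # -- algebra --------------------------------------------------------------
    def intersect(self, other: "RegionSet") -> "RegionSet":
        out: List[GenomicInterval] = []
        for chrom, a in self._by_chrom.items():
            b = other._by_chrom.get(chrom)
            if not b:
                continue
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s <= e:
                    out.append(GenomicInterval(chrom, s, e))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
        return RegionSet(out)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        out: List[GenomicInterval] = []
        for chrom, a in self._by_chrom.items():
            b = other._by_chrom.get(chrom, [])
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j][1] < cur:
                    j += 1
                k = j
                while k < len(b) and b[k][0] <= e:
                    bs, be = b[k]
                    if bs > cur:
                        out.append(GenomicInterval(chrom, cur, bs - 1))
                    cur = max(cur, be + 1)
                    k += 1
                if cur <= e:
                    out.append(GenomicInterval(chrom, cur, e))
        return RegionSet(out)

    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(list(self) + list(other))

    def overlap_bp(self, iv: GenomicInterval) -> int:
        """Bases of ``iv`` covered by this set."""
        spans = self._by_chrom.get(iv.chrom, [])
        total = 0
        for s, e in spans:
            if s > iv.end:
                break
            lo = max(s, iv.start)
            hi = min(e, iv.end)
            if lo <= hi:
                total += hi - lo + 1
        return total


def intersect_region_sets(a: RegionSet, b: RegionSet) -> RegionSet:
    """Bases present in both ``a`` and ``b``."""
    return a.intersect(b)


def subtract_region_sets(a: RegionSet, b: RegionSet) -> RegionSet:
    """Bases in ``a`` and not in ``b``."""
    return a.subtract(b)


def summarize_region_set(r: RegionSet) -> Tuple[int, int]:
    """(interval count, total covered base pairs)."""
    return r.summary()


def overlap_fraction(call: GenomicInterval, mask: RegionSet) -> float:
    """Fraction of ``call`` bases covered by ``mask``, in [0, 1]."""
    return mask.overlap_bp(call) / call.length
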