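"""Canonical genomic interval sets.

All coordinates are 0-based half-open. ``RegionSet`` keeps, per chromosome,
a sorted list of pairwise-disjoint ``(start, end)`` intervals; union,
intersection and subtraction are closed over that canonical form.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Dict, Iterable, Iterator, List, Tuple

Interval = Tuple[int, int]


def _merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and coalesce overlapping or adjacent intervals."""
    out: List[Interval] = []
    for s, e in sorted(intervals):
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class RegionSet:
    """An immutable-by-convention set of genomic intervals.

    Construct from an iterable of ``(chrom, start, end)`` triples; intervals
    are merged into canonical form on ingest.
    """

    def __init__(self, triples: Iterable[Tuple[str, int, int]] = ()) -> None:
        by_chrom: Dict[str, List[Interval]] = {}
        for chrom, s, e in triples:
            by_chrom.setdefault(chrom, []).append((int(s), int(e)))
        self._intervals: Dict[str, List[Interval]] = {
            c: _merge(ivs) for c, ivs in by_chrom.items() if ivs
        }
        self._intervals = {c: ivs for c, ivs in self._intervals.items() if ivs}

    # -- accessors ---------------------------------------------------------

    @property
    def chroms(self) -> List[str]:
        return sorted(self._intervals)

    def intervals(self, chrom: str) -> List[Interval]:
        return list(self._intervals.get(chrom, []))

    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in self.chroms:
            for s, e in self._intervals[chrom]:
                yield chrom, s, e

    def __len__(self) -> int:
        return sum(len(v) for v in self._intervals.values())

    def __bool__(self) -> bool:
        return bool(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __hash__(self) -> int:
        return hash(tuple((c, tuple(ivs)) for c, ivs in sorted(self._intervals.items())))

    def __repr__(self) -> str:
        return f"RegionSet({sum(len(v) for v in self._intervals.values())} intervals, {self.total_bases()} bases)"

    def total_bases(self) -> int:
        return sum(e - s for ivs in self._intervals.values() for s, e in ivs)

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Membership of a single 0-based position."""
        ivs = self._intervals.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        ivs = self._intervals.get(chrom)
        if not ivs or start >= end:
            return False
        i = bisect_right(ivs, (start, float("inf"))) - 1
        if i >= 0 and ivs[i][1] > start:
            return True
        return i + 1 < len(ivs) and ivs[i + 1][0] < end

    # -- algebra -----------------------------------------------------------

    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(list(self) + list(other))

    def intersection(self, other: "RegionSet") -> "RegionSet":
        triples = []
        for chrom in self._intervals:
            a = self._intervals[chrom]
            b = other._intervals.get(chrom)
            if not b:
                continue
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    triples.append((chrom, s, e))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
        return RegionSet(triples)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        triples = []
        for chrom, ivs in self._intervals.items():
            cuts = other._intervals.get(chrom, [])
            for s, e in ivs:
                cur = s
                for cs, ce in cuts:
                    if ce <= cur or cs >= e:
                        continue
                    if cs > cur:
                        triples.append((chrom, cur, cs))
                    cur = max(cur, ce)
                    if cur >= e:
                        break
                if cur < e:
                    triples.append((chrom, cur, e))
        return RegionSet(triples)

    def expand(self, bp: int, chrom_lengths: Dict[str, int] | None = None) -> "RegionSet":
        """Extend every interval by ``bp`` bases on each side (clipped at 0
        and, when known, at the chromosome length)."""
        triples = []
        for chrom, ivs in self._intervals.items():
            limit = chrom_lengths.get(chrom) if chrom_lengths else None
            for s, e in ivs:
                ns = max(0, s - bp)
                ne = e + bp if limit is None else min(limit, e + bp)
                if ns < ne:
                    triples.append((chrom, ns, ne))
        return RegionSet(triples)
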