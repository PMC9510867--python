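"""Core data model for insertion/deletion structural variants.

Coordinates are 0-based half-open throughout the package; VCF I/O converts
to and from 1-based POS at the boundary. Only deletions (DEL) and insertions
(INS) of at least 50 bp are in scope; an insertion occupies a zero-length
span (``end == start``), a deletion spans ``[start, start + svlen)``.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterator

#: Canonical platform/caller labels, in default representative priority order.
PLATFORMS = ("CCS", "CLR", "ONT", "ASM", "BN")

SVTYPES = ("DEL", "INS")
GENOTYPES = ("het", "hom", "unknown")
HAPLOTYPES = ("paternal", "maternal")

#: Minimum size (bp) for a variant to count as structural.
MIN_SV_LEN = 50


@dataclass
class SVRecord:
    """One insertion or deletion call.

    ``support`` holds platform labels that corroborate the call,
    ``hap_support`` the haplotype assemblies (paternal/maternal) that do.
    ``alt_seq`` is the inserted allele for INS, ``ref_seq`` the deleted
    sequence for DEL; both may be empty for symbolic records.
    """

    id: str
    chrom: str
    start: int
    svtype: str
    svlen: int
    alt_seq: str = ""
    ref_seq: str = ""
    support: set = field(default_factory=set)
    hap_support: set = field(default_factory=set)
    genotype: str = "unknown"

    @property
    def end(self) -> int:
        """0-based exclusive end: DEL span end; equals ``start`` for INS."""
        return self.start + self.svlen if self.svtype == "DEL" else self.start

    def span(self) -> tuple[int, int]:
        """Half-open genomic footprint; a point ``[start, start+1)`` for INS.

        Used for interval intersection tests (exclusion regions, CHCR
        containment), where an insertion is anchored at its breakpoint.
        """
        if self.svtype == "DEL":
            return self.start, self.end
        return self.start, self.start + 1

    def validate(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"{self.id}: unknown svtype {self.svtype!r}")
        if self.svlen < 1:
            raise ValueError(f"{self.id}: svlen must be >= 1, got {self.svlen}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"{self.id}: unknown genotype {self.genotype!r}")
        if not self.hap_support <= set(HAPLOTYPES):
            raise ValueError(f"{self.id}: bad hap_support {self.hap_support!r}")

    def copy(self) -> "SVRecord":
        return replace(self, support=set(self.support), hap_support=set(self.hap_support))

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.svtype, self.svlen, self.id)


@dataclass
class Callset:
    """A labelled, position-sorted collection of SVRecords."""

    label: str
    records: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)

    def sort(self) -> "Callset":
        self.records.sort(key=SVRecord.sort_key)
        return self

    def is_sorted(self) -> bool:
        keys = [(r.chrom, r.start) for r in self.records]
        return keys == sorted(keys)

    def copy(self, label: str | None = None) -> "Callset":
        return Callset(
            label if label is not None else self.label,
            [r.copy() for r in self.records],
            dict(self.meta),
        )

    def chroms(self) -> list[str]:
        return sorted({r.chrom for r in self.records})

    def starts_by_chrom(self) -> dict:
        """chrom -> (sorted start array, records in that order); for window queries."""
        out: dict = {}
        for chrom, group in itertools.groupby(
            sorted(self.records, key=SVRecord.sort_key), key=lambda r: r.chrom
        ):
            recs = list(group)
            out[chrom] = ([r.start for r in recs], recs)
        return out


def _merge_sorted(intervals: list) -> list:
    """Merge overlapping or adjacent sorted half-open intervals."""
    merged: list = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


@dataclass
class RegionSet:
    """A set of 0-based half-open genomic intervals (BED semantics)."""

    intervals: list = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def validate(self) -> None:
        for chrom, s, e in self.intervals:
            if s < 0 or s >= e:
                raise ValueError(f"bad interval {chrom}:{s}-{e}")

    def by_chrom(self) -> dict:
        out: dict = {}
        for chrom, s, e in self.intervals:
            out.setdefault(chrom, []).append((s, e))
        for ivs in out.values():
            ivs.sort()
        return out

    def normalize(self) -> "RegionSet":
        """Sort and merge overlapping/adjacent intervals per chromosome."""
        self.validate()
        out = []
        for chrom in sorted(self.by_chrom()):
            for s, e in _merge_sorted(self.by_chrom()[chrom]):
                out.append((chrom, s, e))
        return RegionSet(out, self.label)

    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.normalize().intervals)

    def union(self, other: "RegionSet", label: str = "") -> "RegionSet":
        return RegionSet(list(self.intervals) + list(other.intervals), label).normalize()

    def intersection(self, other: "RegionSet", label: str = "") -> "RegionSet":
        a, b = self.normalize().by_chrom(), other.normalize().by_chrom()
        out = []
        for chrom in sorted(set(a) & set(b)):
            ia, ib = a[chrom], b[chrom]
            i = j = 0
            while i < len(ia) and j < len(ib):
                s = max(ia[i][0], ib[j][0])
                e = min(ia[i][1], ib[j][1])
                if s < e:
                    out.append((chrom, s, e))
                if ia[i][1] <= ib[j][1]:
                    i += 1
                else:
                    j += 1
        return RegionSet(out, label)

    def subtract(self, other: "RegionSet", label: str = "") -> "RegionSet":
        a, b = self.normalize().by_chrom(), other.normalize().by_chrom()
        out = []
        for chrom in sorted(a):
            cuts = b.get(chrom, [])
            for s, e in a[chrom]:
                cur = s
                for cs, ce in cuts:
                    if ce <= cur or cs >= e:
                        continue
                    if cs > cur:
                        out.append((chrom, cur, cs))
                    cur = max(cur, ce)
                    if cur >= e:
                        break
                if cur < e:
                    out.append((chrom, cur, e))
        return RegionSet(out, label)

    def _index(self) -> dict:
        # lazy per-chrom (starts, intervals) cache; treat the set as frozen
        # once queries begin (normalize() returns a fresh object anyway)
        idx = self.__dict__.get("_idx")
        if idx is None:
            idx = {c: ([s for s, _ in ivs], ivs) for c, ivs in self.by_chrom().items()}
            self.__dict__["_idx"] = idx
        return idx

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any interval on chrom (self normalized)."""
        entry = self._index().get(chrom)
        if not entry:
            return False
        starts, ivs = entry
        i = bisect_right(starts, start) - 1
        if i >= 0 and ivs[i][1] > start:
            return True
        # any interval starting strictly inside [start, end)
        return bisect_left(starts, end) > i + 1

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies entirely within one interval."""
        entry = self._index().get(chrom)
        if not entry:
            return False
        starts, ivs = entry
        i = bisect_right(starts, start) - 1
        return i >= 0 and ivs[i][1] >= end
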