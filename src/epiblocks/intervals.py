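"""Genomic interval primitives, BED-style I/O, and the intersection engine.

All coordinates are 0-based half-open internally (BED convention). Table
dialects printed 1-based inclusive (UCSC browser style) are converted on
ingest by the readers (``one_based=True``), never downstream.

Overlap semantics everywhere: two intervals overlap iff they share at least
one base under half-open arithmetic, ``max(starts) < min(ends)``. There is
no minimum-overlap-fraction option.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "IntervalSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "overlaps",
    "count_queries_hit",
    "which_queries_hit",
    "intersect_regions",
]

_VALID_STRANDS = (None, "+", "-")


class BedParseError(ValueError):
    """Raised when a BED-like file contains a malformed record."""


@dataclass(frozen=True)
class GenomicInterval:
    """One chromosome-anchored half-open span; the atom of all overlap work.

    Parameters
    ----------
    chrom
        Chromosome name, e.g. ``"chr9"``. Non-empty, no whitespace.
    start, end
        0-based half-open coordinates; ``0 <= start < end`` so every
        interval covers at least one base.
    name
        Optional label (peak id, rsid, gene symbol).
    strand
        ``"+"``, ``"-"`` or ``None`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if not (0 <= int(self.start) < int(self.end)):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name or "")

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff ``other`` lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def span_1based(self) -> str:
        """Printed 1-based inclusive form, e.g. ``chr4:148365339-148414651``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 base (same chromosome)."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


class ChromSizes(Mapping[str, int]):
    """Mapping chromosome name -> total length in bp."""

    def __init__(self, sizes: Mapping[str, int]):
        cleaned = {}
        for chrom, size in sizes.items():
            size = int(size)
            if size < 1:
                raise ValueError(f"chromosome {chrom!r} has length {size} < 1")
            cleaned[str(chrom)] = size
        self._sizes = cleaned

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def validate(self, interval: GenomicInterval) -> None:
        """Raise if the interval's chromosome is unknown or it runs past the end."""
        if interval.chrom not in self._sizes:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self._sizes[interval.chrom]:
            raise ValueError(
                f"interval {interval.chrom}:[{interval.start},{interval.end}) "
                f"exceeds chromosome length {self._sizes[interval.chrom]}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromSizes":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise BedParseError(f"{path}:{lineno}: expected 'name length'")
                try:
                    sizes[fields[0]] = int(fields[1])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
        return cls(sizes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, size in self._sizes.items():
                fh.write(f"{chrom}\t{size}\n")


class _ChromIndex:
    """Merged, sorted per-chromosome coverage used for fast hit queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self.merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda x: (x.start, x.end))
            starts: list[int] = []
            ends: list[int] = []
            for iv in ivs:
                if ends and iv.start < ends[-1]:
                    # extends the current merged run (touching runs stay split:
                    # abutting intervals share no base and never co-hit a query)
                    if iv.end > ends[-1]:
                        ends[-1] = iv.end
                else:
                    starts.append(iv.start)
                    ends.append(iv.end)
            self.merged[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )

    def hits(self, chrom: str, qstart: np.ndarray, qend: np.ndarray) -> np.ndarray:
        """Vectorized: which of the half-open queries touch >= 1 base of coverage."""
        if chrom not in self.merged:
            return np.zeros(len(qstart), dtype=bool)
        starts, ends = self.merged[chrom]
        if len(starts) == 0:
            return np.zeros(len(qstart), dtype=bool)
        # candidate run: the last merged run starting before the query end
        idx = np.searchsorted(starts, qend, side="left")
        hit = idx > 0
        hit[hit] = ends[idx[hit] - 1] > qstart[hit]
        return hit


class IntervalSet:
    """Deterministically ordered collection of :class:`GenomicInterval`.

    Iteration order is sorted by (chrom lexicographic, start, end, name).
    Duplicates are allowed (they can arise from pairwise intersection).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=GenomicInterval.sort_key)
        )
        self._index: _ChromIndex | None = None
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __bool__(self) -> bool:
        return bool(self._intervals)

    def __contains__(self, iv: GenomicInterval) -> bool:
        return iv in self._intervals

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __hash__(self) -> int:
        return hash(self._intervals)

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(iv.chrom for iv in self._intervals))

    @property
    def index(self) -> _ChromIndex:
        if self._index is None:
            self._index = _ChromIndex(self._intervals)
        return self._index

    def trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self._intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees

    def overlaps_interval(self, query: GenomicInterval) -> bool:
        """True iff any member overlaps the query."""
        hit = self.index.hits(
            query.chrom,
            np.asarray([query.start], dtype=np.int64),
            np.asarray([query.end], dtype=np.int64),
        )
        return bool(hit[0])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self],
                "start": [iv.start for iv in self],
                "end": [iv.end for iv in self],
                "name": [iv.name for iv in self],
                "strand": [iv.strand for iv in self],
            }
        )


def _as_intervals(queries) -> list[GenomicInterval]:
    out = []
    for q in queries:
        if isinstance(q, GenomicInterval):
            out.append(q)
        elif hasattr(q, "interval"):
            out.append(q.interval)
        else:
            raise TypeError(f"not an interval: {q!r}")
    return out


def which_queries_hit(queries, peaks: IntervalSet) -> np.ndarray:
    """Boolean array, aligned with query order: does each query touch >= 1 peak?"""
    qs = _as_intervals(queries)
    result = np.zeros(len(qs), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, q in enumerate(qs):
        by_chrom.setdefault(q.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        qstart = np.asarray([qs[i].start for i in idxs], dtype=np.int64)
        qend = np.asarray([qs[i].end for i in idxs], dtype=np.int64)
        result[np.asarray(idxs)] = peaks.index.hits(chrom, qstart, qend)
    return result


def count_queries_hit(queries, peaks: IntervalSet) -> int:
    """Number of query intervals overlapping >= 1 peak (each counted once)."""
    return int(which_queries_hit(queries, peaks).sum())


def intersect_regions(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Clipped pairwise intersections of two interval sets.

    Each overlapping (a, b) pair contributes one interval spanning the shared
    bases; the result interval inherits the name of the ``a`` member, which
    lets callers keep track of which source region a fragment came from.
    """
    trees = b.trees()
    out: list[GenomicInterval] = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            out.append(
                GenomicInterval(
                    chrom=iv.chrom,
                    start=max(iv.start, hit.begin),
                    end=min(iv.end, hit.end),
                    name=iv.name,
                )
            )
    return IntervalSet(out)


def read_bed(path: str | Path, one_based: bool = False) -> IntervalSet:
    """Read a BED3/BED4/BED6-like file into an :class:`IntervalSet`.

    ``one_based=True`` selects the 1-based inclusive table dialect (printed
    UCSC-style coordinates): starts are shifted down by one on ingest so the
    stored span covers the same bases half-open. Track/browser/comment lines
    are skipped. Zero-length records are rejected: they cannot overlap
    anything and usually indicate a dialect error.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from exc
            if one_based:
                start -= 1
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(interval_set: IntervalSet, path: str | Path) -> None:
    """Write standard BED (0-based half-open, tab-separated, sorted order)."""
    with open(path, "w") as fh:
        for iv in interval_set:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.strand is not None:
                fields += [iv.name or ".", "0", iv.strand]
            elif iv.name is not None:
                fields.append(iv.name)
            fh.write("\t".join(fields) + "\n")
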