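"""Genomic interval algebra and BED I/O.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  "One bp overlap" therefore means an intersection of
length >= 1 base, so abutting intervals (``a.end == b.start``) do NOT
overlap.  Chromosome names are matched by exact string comparison; no
"chr" prefix normalisation is attempted (callers harmonise naming
upstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence


class BedParseError(ValueError):
    """Raised when a BED record cannot be parsed; carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name (non-empty).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    mark : str
        Source label, e.g. the ChIP antibody ("survivin", "H3K27ac") or
        "region" for derived co-deposition spans.
    score : float, optional
        Non-negative score.  For called peaks this is the upstream peak
        score (consumed, never computed here); for merged regions it is
        the number of member peaks.
    """

    chrom: str
    start: int
    end: int
    mark: str = ""
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise ValueError("start/end must be integers")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError("score must be non-negative")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Length of the intersection with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class PeakSet:
    """An immutable, sorted, deduplicated collection of intervals.

    Duplicates (identical ``(chrom, start, end, mark)``) are collapsed on
    construction; intervals are kept sorted by ``(chrom, start, end)``.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], source: str = "") -> None:
        seen: dict[tuple, GenomicInterval] = {}
        for iv in intervals:
            seen.setdefault((iv.chrom, iv.start, iv.end, iv.mark), iv)
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(seen.values(), key=lambda iv: (iv.chrom, iv.start, iv.end, iv.mark))
        )
        self.source = source

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PeakSet(n={len(self)}, source={self.source!r})"

    def spans(self) -> list[tuple[str, int, int]]:
        """Bare ``(chrom, start, end)`` triples, sorted."""
        return [(iv.chrom, iv.start, iv.end) for iv in self.intervals]


def read_bed(path: str | Path, source: str | None = None) -> PeakSet:
    """Read a BED3/BED5 file into a :class:`PeakSet`.

    Columns beyond the third are optional: column 4 is taken as the mark
    label, column 5 as the score.  Comment lines (``#``, ``track``,
    ``browser``) are skipped.  An empty file yields an empty set.

    Raises
    ------
    BedParseError
        On non-integer coordinates, ``start >= end`` or fewer than three
        columns; the message names the offending line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            mark = fields[3] if len(fields) > 3 else ""
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score") from exc
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, mark=mark, score=score)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals, source=source if source is not None else str(path))


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a :class:`PeakSet` as BED5 (name = mark, score column optional)."""
    with open(path, "w") as fh:
        for iv in peaks:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.mark or "."]
            if iv.score is not None:
                cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


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


def _connected_components(
    intervals: Sequence[GenomicInterval], min_overlap: int
) -> list[list[GenomicInterval]]:
    """Components of the graph whose edges join interval pairs with
    intersection length >= ``min_overlap``.  Sweep line with pruning:
    once a seen interval's end falls below ``start + min_overlap`` of the
    current sweep position it can never connect to a later interval."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    components: list[list[GenomicInterval]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        uf = _UnionFind(len(ivs))
        active: list[int] = []
        for i, iv in enumerate(ivs):
            active = [j for j in active if ivs[j].end - iv.start >= min_overlap]
            if len(iv) >= min_overlap:
                for j in active:
                    if min(ivs[j].end, iv.end) - iv.start >= min_overlap:
                        uf.union(i, j)
            active.append(i)
        groups: dict[int, list[GenomicInterval]] = {}
        for i, iv in enumerate(ivs):
            groups.setdefault(uf.find(i), []).append(iv)
        components.extend(groups[r] for r in sorted(groups, key=lambda r: ivs[r].start))
    return components


def merge_overlapping(peaks: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Merge intervals into connected-component union spans.

    Two intervals are connected when their intersection is at least
    ``min_overlap`` bases; each connected component is replaced by the
    span ``[min(start), max(end))`` of its members.  With the default
    ``min_overlap=1`` components are contiguous, the output is pairwise
    non-overlapping, and the covered bases are preserved exactly.  For
    ``min_overlap > 1`` distinct components may overlap by fewer than
    ``min_overlap`` bases and are returned as-is.

    The merged interval keeps the members' mark when unique (else
    ``"merged"``) and carries the member count as its score.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    merged: list[GenomicInterval] = []
    for comp in _connected_components(peaks.intervals, min_overlap):
        marks = {iv.mark for iv in comp}
        merged.append(
            GenomicInterval(
                comp[0].chrom,
                min(iv.start for iv in comp),
                max(iv.end for iv in comp),
                mark=marks.pop() if len(marks) == 1 else "merged",
                score=float(len(comp)),
            )
        )
    return PeakSet(merged, source=peaks.source)


def codeposition_regions(a: PeakSet, b: PeakSet) -> PeakSet:
    """Regions where two chromatin marks are co-deposited.

    Builds the >= 1 bp overlap graph over the pooled peaks of both marks,
    takes connected components, discards components containing a single
    mark only, and returns each remaining component's union span with
    mark ``"region"`` and score = number of member peaks.  Symmetric in
    its arguments.
    """
    if len(a) == 0 or len(b) == 0:
        warnings.warn("codeposition_regions: an input peak set is empty")
        return PeakSet([], source="codeposition")
    marks_a = {iv.mark for iv in a}
    marks_b = {iv.mark for iv in b}
    if marks_a & marks_b:
        raise ValueError(
            f"peak sets must carry distinct marks, both contain {marks_a & marks_b}"
        )
    pooled = [replace(iv, mark=f"a::{iv.mark}") for iv in a]
    pooled += [replace(iv, mark=f"b::{iv.mark}") for iv in b]
    regions: list[GenomicInterval] = []
    for comp in _connected_components(pooled, min_overlap=1):
        sides = {iv.mark.split("::", 1)[0] for iv in comp}
        if sides == {"a", "b"}:
            regions.append(
                GenomicInterval(
                    comp[0].chrom,
                    min(iv.start for iv in comp),
                    max(iv.end for iv in comp),
                    mark="region",
                    score=float(len(comp)),
                )
            )
    return PeakSet(regions, source="codeposition")
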