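"""Genomic-interval engine and BED I/O.

All coordinates are 0-based half-open (BED convention). Chromosome name
matching is exact-string; :func:`normalize_chrom` is provided for inputs
that disagree about the ``chr`` prefix.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "intersect_intervals",
    "promoter_windows",
    "assign_points_to_peaks",
    "normalize_chrom",
    "read_gene_annotation",
    "write_gene_annotation",
]

_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised for malformed BED lines; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "requires 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand code {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        """True if the two intervals share at least ``min_bp`` bases."""
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class PeakSet:
    """An ordered collection of intervals for one factor/cell track.

    ``intervals`` is always kept sorted by (chrom, start, end). When
    ``merged`` is true no two intervals on the same chromosome overlap.
    """

    label: str
    intervals: list[GenomicInterval]
    merged: bool = False

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        if self.merged and self._has_same_chrom_overlap():
            raise ValueError("merged PeakSet contains overlapping intervals")

    def _has_same_chrom_overlap(self) -> bool:
        for prev, cur in zip(self.intervals, self.intervals[1:]):
            if prev.chrom == cur.chrom and cur.start < prev.end:
                return True
        return False

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bases(self) -> int:
        """Covered bases; counts overlap-duplicated bases once."""
        total = 0
        for ivs in self.by_chrom().values():
            cur_start, cur_end = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_end:
                    cur_end = max(cur_end, iv.end)
                else:
                    total += cur_end - cur_start
                    cur_start, cur_end = iv.start, iv.end
            total += cur_end - cur_start
        return total


def normalize_chrom(chrom: str, style: str = "chr") -> str:
    """Normalize the ``chr`` prefix of a chromosome name.

    style="chr" ensures the prefix is present; style="plain" strips it.
    """
    if style == "chr":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    if style == "plain":
        return chrom[3:] if chrom.startswith("chr") else chrom
    raise ValueError(f"unknown chromosome-name style {style!r}")


def read_bed(path: str | Path, label: str | None = None) -> PeakSet:
    """Read a BED3/BED6 file into a sorted :class:`PeakSet`.

    Track/browser/comment lines are skipped. Columns 4-6, when present,
    map to name/score/strand ('.' score treated as missing).
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(label=label or path.stem, intervals=intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED; emits 6 columns when any optional field is set."""
    six = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in peaks
    )
    with open(path, "w") as fh:
        for iv in peaks:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def merge_intervals(peaks: PeakSet) -> PeakSet:
    """Union overlapping or book-ended intervals per chromosome.

    Idempotent; preserves total covered bases.
    """
    merged: list[GenomicInterval] = []
    for chrom, ivs in peaks.by_chrom().items():
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return PeakSet(label=peaks.label, intervals=merged, merged=True)


def intersect_intervals(
    a: PeakSet, b: PeakSet, min_overlap: int = 1
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All pairs (interval-in-a, interval-in-b) overlapping by >= min_overlap bp.

    Sweep over the sorted per-chromosome lists; each overlapping pair is
    reported exactly once, in (a, b) sorted order.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    b_by_chrom = b.by_chrom()
    for chrom, a_ivs in a.by_chrom().items():
        b_ivs = b_by_chrom.get(chrom)
        if not b_ivs:
            continue
        b_starts = [iv.start for iv in b_ivs]
        # non-decreasing prefix max of ends bounds the candidate range below
        prefix_max_end = []
        m = 0
        for iv in b_ivs:
            m = max(m, iv.end)
            prefix_max_end.append(m)
        for ia in a_ivs:
            lo = bisect.bisect_right(prefix_max_end, ia.start + min_overlap - 1)
            hi = bisect.bisect_left(b_starts, ia.end - min_overlap + 1)
            for ib in b_ivs[lo:hi]:
                if min(ia.end, ib.end) - max(ia.start, ib.start) >= min_overlap:
                    pairs.append((ia, ib))
    return pairs


def promoter_windows(
    genes: pd.DataFrame, flank: int = 5000, label: str = "promoters"
) -> PeakSet:
    """Symmetric promoter windows ``[max(0, tss-flank), tss+flank)`` per gene.

    ``genes`` columns: gene, chrom, tss, strand. The window ignores strand
    (symmetric); the start is clipped at the chromosome origin.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    if genes["gene"].duplicated().any():
        raise ValueError("gene symbols must be unique in the annotation table")
    intervals = []
    for row in genes.itertuples(index=False):
        if row.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand code {row.strand!r} for {row.gene}")
        tss = int(row.tss)
        if tss < 0:
            raise ValueError(f"negative tss for {row.gene}")
        intervals.append(
            GenomicInterval(
                row.chrom, max(0, tss - flank), tss + flank, name=row.gene
            )
        )
    return PeakSet(label=label, intervals=intervals)


def assign_points_to_peaks(
    points: Iterable[tuple[str, int]], peaks: PeakSet
) -> np.ndarray:
    """Boolean flag per point: inside some interval (start <= pos < end).

    Membership is evaluated on the merged set, which is equivalent for
    any-interval containment.
    """
    merged = peaks if peaks.merged else merge_intervals(peaks)
    by_chrom = {
        chrom: (np.array([iv.start for iv in ivs]), np.array([iv.end for iv in ivs]))
        for chrom, ivs in merged.by_chrom().items()
    }
    points = list(points)
    flags = np.zeros(len(points), dtype=bool)
    for i, (chrom, pos) in enumerate(points):
        se = by_chrom.get(chrom)
        if se is None:
            continue
        starts, ends = se
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        flags[i] = j >= 0 and pos < ends[j]
    return flags


def subtract_intervals(a: PeakSet, b: PeakSet) -> PeakSet:
    """Portions of (merged) a not covered by b, as a merged PeakSet."""
    a_m = a if a.merged else merge_intervals(a)
    b_m = b if b.merged else merge_intervals(b)
    b_by_chrom = b_m.by_chrom()
    out: list[GenomicInterval] = []
    for chrom, a_ivs in a_m.by_chrom().items():
        b_ivs = b_by_chrom.get(chrom, [])
        for ia in a_ivs:
            cursor = ia.start
            for ib in b_ivs:
                if ib.end <= cursor or ib.start >= ia.end:
                    continue
                if ib.start > cursor:
                    out.append(GenomicInterval(chrom, cursor, ib.start))
                cursor = max(cursor, ib.end)
                if cursor >= ia.end:
                    break
            if cursor < ia.end:
                out.append(GenomicInterval(chrom, cursor, ia.end))
    return PeakSet(label=f"{a.label}-minus-{b.label}", intervals=out, merged=True)


def intersection_regions(a: PeakSet, b: PeakSet) -> PeakSet:
    """Base-level intersection of two (merged) peak sets, as a merged PeakSet."""
    a_m = a if a.merged else merge_intervals(a)
    b_m = b if b.merged else merge_intervals(b)
    out = [
        GenomicInterval(ia.chrom, max(ia.start, ib.start), min(ia.end, ib.end))
        for ia, ib in intersect_intervals(a_m, b_m)
    ]
    return PeakSet(label=f"{a.label}-and-{b.label}", intervals=out, merged=True)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV with columns gene, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    df["tss"] = df["tss"].astype(int)
    return df


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)
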