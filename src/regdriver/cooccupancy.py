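"""Two-factor chromatin co-occupancy classification and peak filtering."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from regdriver.intervals import (
    GenomicInterval,
    PeakSet,
    intersect_intervals,
    merge_intervals,
)

__all__ = [
    "CooccupancyResult",
    "classify_cooccupancy",
    "filter_differential_peaks",
    "read_scored_peaks",
    "write_labeled_bed",
]


@dataclass
class CooccupancyResult:
    """Common/unique classification of two merged peak sets.

    fraction_a (fraction_b) is the share of A (B) peaks overlapped by at
    least one peak of the other set; nan when the set is empty.
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_common_a: int
    n_common_b: int
    labels_a: list[str] = field(repr=False, default_factory=list)
    labels_b: list[str] = field(repr=False, default_factory=list)
    peaks_a: PeakSet | None = field(repr=False, default=None)
    peaks_b: PeakSet | None = field(repr=False, default=None)

    @property
    def fraction_a(self) -> float:
        return self.n_common_a / self.n_a if self.n_a else math.nan

    @property
    def fraction_b(self) -> float:
        return self.n_common_b / self.n_b if self.n_b else math.nan

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set": [self.label_a, self.label_b],
                "n_peaks": [self.n_a, self.n_b],
                "n_common": [self.n_common_a, self.n_common_b],
                "n_unique": [self.n_a - self.n_common_a, self.n_b - self.n_common_b],
                "fraction_common": [self.fraction_a, self.fraction_b],
            }
        )


def classify_cooccupancy(
    a: PeakSet,
    b: PeakSet,
    min_overlap: int = 1,
    summit_distance: int | None = None,
) -> CooccupancyResult:
    """Label each peak of two sets as common or unique.

    Both sets are merged internally if not already. A peak is *common*
    when it overlaps >= ``min_overlap`` bp of some peak in the other set.
    ``summit_distance`` switches to a center-distance criterion (centers
    within d bp) instead of interval overlap; off by default.
    """
    a_m = a if a.merged else merge_intervals(a)
    b_m = b if b.merged else merge_intervals(b)
    common_a: set[GenomicInterval] = set()
    common_b: set[GenomicInterval] = set()
    if summit_distance is None:
        for ia, ib in intersect_intervals(a_m, b_m, min_overlap=min_overlap):
            common_a.add(ia)
            common_b.add(ib)
    else:
        b_centers = [((iv.start + iv.end) // 2, iv) for iv in b_m]
        for ia in a_m:
            ca = (ia.start + ia.end) // 2
            for cb, ib in b_centers:
                if ia.chrom == ib.chrom and abs(ca - cb) <= summit_distance:
                    common_a.add(ia)
                    common_b.add(ib)
    labels_a = ["common" if iv in common_a else "unique" for iv in a_m]
    labels_b = ["common" if iv in common_b else "unique" for iv in b_m]
    return CooccupancyResult(
        label_a=a_m.label,
        label_b=b_m.label,
        n_a=len(a_m),
        n_b=len(b_m),
        n_common_a=len(common_a),
        n_common_b=len(common_b),
        labels_a=labels_a,
        labels_b=labels_b,
        peaks_a=a_m,
        peaks_b=b_m,
    )


def filter_differential_peaks(
    peaks: pd.DataFrame, p_max: float = 1e-4, fc_min: float = 4.0
) -> pd.DataFrame:
    """Keep peaks with p_value < p_max AND fold_change > fc_min (both strict)."""
    for col in ("p_value", "fold_change"):
        if col not in peaks.columns:
            raise ValueError(f"scored peak table missing column {col!r}")
        bad = peaks[col].isna()
        if bad.any():
            idx = peaks.index[bad][0]
            raise ValueError(f"peak {idx!r} is missing {col}")
    keep = (peaks["p_value"] < p_max) & (peaks["fold_change"] > fc_min)
    return peaks.loc[keep].copy()


def read_scored_peaks(path: str | Path) -> pd.DataFrame:
    """Read BED6+2 scored peaks (extra columns: p_value, fold_change)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "chrom",
            "start",
            "end",
            "name",
            "score",
            "strand",
            "p_value",
            "fold_change",
        ],
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: interval with start >= end")
    return df


def write_labeled_bed(result: CooccupancyResult, path: str | Path) -> None:
    """Three-way labeled BED export: A-unique / common / B-unique."""
    assert result.peaks_a is not None and result.peaks_b is not None
    with open(path, "w") as fh:
        for iv, lab in zip(result.peaks_a, result.labels_a):
            tag = "common" if lab == "common" else f"{result.label_a}_unique"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{tag}\n")
        for iv, lab in zip(result.peaks_b, result.labels_b):
            if lab == "common":
                continue  # the common category is emitted once, from A
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{result.label_b}_unique\n")
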