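"""Genomic interval sets in 0-based, half-open coordinates.

All coverage bookkeeping in the package goes through :class:`IntervalSet`,
so that the one place where VCF (1-based) positions meet BED (0-based,
half-open) intervals is :func:`vcf_pos_to_zero_based`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntervalSet",
    "vcf_pos_to_zero_based",
    "intersect_coverage",
    "overlap_stats",
    "OverlapStats",
]


def vcf_pos_to_zero_based(pos: int) -> int:
    """Convert a 1-based VCF POS to a 0-based coordinate."""
    if pos < 1:
        raise ValueError(f"VCF positions are 1-based; got {pos}")
    return pos - 1


@dataclass
class IntervalSet:
    """Per-contig covered regions, normalized to sorted non-overlapping intervals.

    ``intervals`` maps contig id to a list of ``(start, end)`` pairs in
    0-based half-open coordinates; ``end > start`` always holds after
    normalization.
    """

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {
            contig: _normalize(ivs) for contig, ivs in self.intervals.items()
        }

    @classmethod
    def from_pairs(cls, contig: str, pairs: Iterable[tuple[int, int]]) -> "IntervalSet":
        return cls({contig: list(pairs)})

    @classmethod
    def read_bed(cls, path: str | Path) -> "IntervalSet":
        """Read a BED3 file (extra columns ignored)."""
        table = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["contig", "start", "end"], usecols=[0, 1, 2],
            dtype={"contig": str, "start": np.int64, "end": np.int64},
        )
        out: dict[str, list[tuple[int, int]]] = {}
        for contig, sub in table.groupby("contig", sort=False):
            out[str(contig)] = list(zip(sub["start"], sub["end"]))
        return cls(out)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig in self.intervals:
                for start, end in self.intervals[contig]:
                    fh.write(f"{contig}\t{start}\t{end}\n")

    def contigs(self) -> list[str]:
        return list(self.intervals)

    def iter_intervals(self) -> Iterator[tuple[str, int, int]]:
        for contig, ivs in self.intervals.items():
            for start, end in ivs:
                yield contig, start, end

    def total_bases(self) -> int:
        return sum(end - start for _, start, end in self.iter_intervals())

    def n_regions(self) -> int:
        return sum(len(ivs) for ivs in self.intervals.values())

    def contains_window(self, contig: str, start: int, end: int) -> bool:
        """True iff [start, end) lies entirely within one covered interval."""
        ivs = self.intervals.get(contig)
        if not ivs or end <= start:
            return False
        starts = [iv[0] for iv in ivs]
        # rightmost interval starting at or before `start`
        import bisect

        i = bisect.bisect_right(starts, start) - 1
        if i < 0:
            return False
        return ivs[i][1] >= end

    def contains_point(self, contig: str, pos: int) -> bool:
        return self.contains_window(contig, pos, pos + 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = {c: ivs for c, ivs in self.intervals.items() if ivs}
        b = {c: ivs for c, ivs in other.intervals.items() if ivs}
        return a == b


def _normalize(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort, drop empty intervals, and merge overlapping/adjacent ones."""
    cleaned = sorted((int(s), int(e)) for s, e in pairs if e > s)
    merged: list[tuple[int, int]] = []
    for start, end in cleaned:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _intersect_two(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        start = max(a[i][0], b[j][0])
        end = min(a[i][1], b[j][1])
        if end > start:
            out.append((start, end))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_coverage(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Maximal regions covered in *every* input set.

    1 bp overlaps are legal output; disjoint inputs yield an empty set.
    Associative and commutative; the per-contig sweep intersects pairwise.
    """
    if len(sets) < 1:
        raise ValueError("need at least one interval set")
    common = set(sets[0].intervals)
    for s in sets[1:]:
        common &= set(s.intervals)
    out: dict[str, list[tuple[int, int]]] = {}
    for contig in sorted(common):
        acc = sets[0].intervals[contig]
        for s in sets[1:]:
            acc = _intersect_two(acc, s.intervals[contig])
            if not acc:
                break
        if acc:
            out[contig] = acc
    return IntervalSet(out)


@dataclass
class OverlapStats:
    """Region-length summary (min/median/mean/max in bp) of a shared interval set."""

    n_regions: int
    min_length: int | None
    median_length: float | None
    mean_length: float | None
    max_length: int | None

    def to_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "min_length": self.min_length,
            "median_length": self.median_length,
            "mean_length": self.mean_length,
            "max_length": self.max_length,
        }


def overlap_stats(shared: IntervalSet) -> OverlapStats:
    lengths = np.array(
        [end - start for _, start, end in shared.iter_intervals()], dtype=np.int64
    )
    if lengths.size == 0:
        return OverlapStats(0, None, None, None, None)
    return OverlapStats(
        n_regions=int(lengths.size),
        min_length=int(lengths.min()),
        median_length=float(np.median(lengths)),
        mean_length=float(lengths.mean()),
        max_length=int(lengths.max()),
    )
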