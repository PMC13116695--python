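"""Variant-retention cascade over a multi-sample VCF plus coverage intervals.

Stages, in order: site class (keep biallelic SNVs), per-sample depth
(DP > 10), fixed-between-species removal, flanking-sequence quality
(20 bp covered, variant-free, N-free on each side), and call rate
(>= 0.5, i.e. genotyped in at least two of four samples).  Every stage
shrinks the table monotonically and the report reconciles exactly:
``out = in - removed`` at each stage and stages chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .intervals import IntervalSet
from .variants import VariantRecord, VariantTable, read_vcf

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "classify_site",
    "depth_filter",
    "call_rate",
    "call_rate_filter",
    "fixed_filter",
    "flank_filter",
    "quality_fail",
    "run_cascade",
]


@dataclass(frozen=True)
class FilterThresholds:
    """All cascade thresholds in one place.

    ``min_depth_exclusive`` is strict (DP > 10 keeps DP = 11 and up);
    ``min_cr`` is inclusive (call rate 0.5 = two of four samples is kept).
    """

    min_depth_exclusive: int = 10
    window: int = 20
    t_low: float = 0.1
    t_high: float = 0.9
    min_cr: float = 0.5
    min_site_quality: float = 20.0  # used by the optional quality predicate only

    def validate(self) -> None:
        if not (0.0 <= self.t_low < self.t_high <= 1.0):
            raise ValueError(
                f"need 0 <= t_low < t_high <= 1, got {self.t_low}, {self.t_high}"
            )
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if not (0.0 <= self.min_cr <= 1.0):
            raise ValueError("min_cr must be in [0, 1]")


@dataclass
class FilterReport:
    """Per-stage accounting; ``out = in - removed`` everywhere, stages chain."""

    stages: list[dict] = field(default_factory=list)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)

    def add(self, name: str, n_in: int, n_removed: int) -> None:
        if self.stages and self.stages[-1]["n_out"] != n_in:
            raise ValueError(
                f"stage {name!r} input {n_in} does not chain from previous "
                f"output {self.stages[-1]['n_out']}"
            )
        self.stages.append(
            {"stage": name, "n_in": n_in, "n_removed": n_removed, "n_out": n_in - n_removed}
        )

    @property
    def n_retained(self) -> int:
        return self.stages[-1]["n_out"] if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_json(self) -> str:
        return json.dumps(
            {"thresholds": asdict(self.thresholds), "stages": self.stages}, indent=2
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(self.to_json())
        else:
            self.to_frame().to_csv(path, sep="\t", index=False)


def classify_site(v: VariantRecord) -> str:
    """biallelic_snv | indel | multiallelic (one alt, both alleles 1 bp)."""
    return v.site_class()


def quality_fail(v: VariantRecord, min_site_quality: float = 20.0) -> bool:
    """Configurable site-quality predicate (default: QUAL < 20 fails).

    The quality category in reference-evaluation reports has no canonical
    definition; this predicate is reported as applied, nothing more.
    """
    return v.qual is not None and v.qual < min_site_quality


def site_class_filter(table: VariantTable) -> VariantTable:
    return table.subset(r for r in table if r.site_class() == "biallelic_snv")


def depth_filter(table: VariantTable, min_depth_exclusive: int = 10) -> VariantTable:
    """Keep variants with DP strictly above the threshold in every
    non-missing sample; a missing DP value fails for that sample."""

    def passes(r: VariantRecord) -> bool:
        for s in table.samples:
            c = r.calls.get(s)
            if c is None or c.is_missing:
                continue
            if c.dp is None or c.dp <= min_depth_exclusive:
                return False
        return True

    return table.subset(r for r in table if passes(r))


def call_rate(v: VariantRecord, n_samples: int) -> float:
    """Fraction of samples with a non-missing genotype."""
    return v.call_rate(n_samples)


def call_rate_filter(table: VariantTable, min_cr: float = 0.5) -> VariantTable:
    n = len(table.samples)
    if n == 0:
        raise ValueError("table has no samples")
    return table.subset(r for r in table if r.call_rate(n) >= min_cr)


def fixed_filter(
    table: VariantTable, t_low: float = 0.1, t_high: float = 0.9
) -> VariantTable:
    """Remove variants fixed across species: all non-missing alt-allele
    fractions >= t_high, or all <= t_low; no informative sample also removes."""

    def passes(r: VariantRecord) -> bool:
        fracs = [f for f in r.alt_fractions(table.samples) if f is not None]
        if not fracs:
            return False  # "no data"
        if all(f >= t_high for f in fracs):
            return False
        if all(f <= t_low for f in fracs):
            return False
        return True

    return table.subset(r for r in table if passes(r))


def flank_filter(
    table: VariantTable,
    coverage: Mapping[str, IntervalSet],
    window: int = 20,
    reference: Mapping[str, str] | None = None,
) -> VariantTable:
    """Keep variants whose closed ±window flank is high quality everywhere.

    High quality means: fully inside a covered interval for every sample
    with coverage data, no other candidate variant within ``window`` bp on
    either side (mutual violations remove both), and no N in the reference
    window when a reference is supplied.
    """
    positions: dict[str, list[int]] = {}
    for r in table:
        positions.setdefault(r.contig, []).append(r.pos)

    def passes(r: VariantRecord) -> bool:
        pos0 = r.pos - 1
        lo0, hi0 = pos0 - window, pos0 + window + 1  # half-open
        if lo0 < 0:
            return False  # window protrudes past the contig start
        for ivset in coverage.values():
            if r.contig not in ivset.intervals:
                return False  # "uncovered"
            if not ivset.contains_window(r.contig, lo0, hi0):
                return False
        for other_pos in positions.get(r.contig, ()):
            if other_pos != r.pos and abs(other_pos - r.pos) <= window:
                return False
        if reference is not None:
            seq = reference.get(r.contig)
            if seq is None:
                return False
            if "N" in seq[max(0, lo0): hi0].upper():
                return False
        return True

    return table.subset(r for r in table if passes(r))


def run_cascade(
    vcf: VariantTable | str | Path,
    coverage: Mapping[str, IntervalSet],
    thresholds: FilterThresholds | None = None,
    reference: Mapping[str, str] | None = None,
) -> tuple[VariantTable, FilterReport]:
    """Apply site-class, depth, fixed, flank and call-rate stages in order."""
    thresholds = thresholds or FilterThresholds()
    thresholds.validate()
    table = vcf if isinstance(vcf, VariantTable) else read_vcf(vcf)
    report = FilterReport(thresholds=thresholds)

    stages: Sequence[tuple[str, callable]] = [
        ("site_class", lambda t: site_class_filter(t)),
        ("depth", lambda t: depth_filter(t, thresholds.min_depth_exclusive)),
        ("fixed", lambda t: fixed_filter(t, thresholds.t_low, thresholds.t_high)),
        ("flank", lambda t: flank_filter(t, coverage, thresholds.window, reference)),
        ("call_rate", lambda t: call_rate_filter(t, thresholds.min_cr)),
    ]
    for name, fn in stages:
        n_in = len(table)
        table = fn(table)
        report.add(name, n_in, n_in - len(table))
    return table, report
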