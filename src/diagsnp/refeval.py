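"""Reference-genome comparison metrics and shared-region statistics.

For each candidate reference the same variant table is summarised by
category (indel/multiallelic, low depth, quality, fixed, common among the
species, call-rate pass) using the filtering module's predicates, each
applied to the full set independently.  Shared coverage across species is
intersected and its region-length distribution summarised.  The TOP100
concordance compares, per principal component, the 100 largest-|loading|
variants under two filtering strategies: (i) call rate >= 0.5 and
(ii) variants called in every sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dosage import build_dosage, scale_center
from .filtering import FilterThresholds, quality_fail
from .intervals import IntervalSet, OverlapStats, intersect_coverage, overlap_stats
from .model import pca, rank_informative
from .variants import VariantTable

__all__ = [
    "ReferenceEvalReport",
    "evaluate_reference",
    "rank_references",
    "intersect_coverage",
    "overlap_stats",
]


@dataclass
class ReferenceEvalReport:
    """Per-reference variant-category counts and TOP100 concordance."""

    reference_id: str
    total_variants: int
    indel_multiallelic: int
    low_depth: int
    quality_fail_count: int
    fixed: int
    common_among_species: int
    cr_pass: int
    top_concordance: dict[int, int] = field(default_factory=dict)
    overlap: OverlapStats | None = None

    @property
    def top_concordance_total(self) -> int:
        return sum(self.top_concordance.values())

    def proportions(self) -> dict[str, float]:
        """Category proportions recomputed from the counts."""
        t = self.total_variants
        if t == 0:
            return {}
        return {
            "indel_multiallelic": self.indel_multiallelic / t,
            "low_depth": self.low_depth / t,
            "quality_fail": self.quality_fail_count / t,
            "fixed": self.fixed / t,
        }

    def to_json(self) -> str:
        d = asdict(self)
        d["top_concordance_total"] = self.top_concordance_total
        d["proportions"] = self.proportions()
        return json.dumps(d, indent=2)


def _top100_concordance(
    table: VariantTable, thresholds: FilterThresholds, k: int = 100,
    components: Sequence[int] = (1, 2),
) -> dict[int, int]:
    """|top-k(PC) under CR strategy ∩ top-k(PC) under all-called strategy|."""
    n = len(table.samples)
    cr_set = table.subset(r for r in table
                          if r.site_class() == "biallelic_snv"
                          and r.call_rate(n) >= thresholds.min_cr)
    full_set = table.subset(r for r in table
                            if r.site_class() == "biallelic_snv"
                            and r.call_rate(n) == 1.0)
    out: dict[int, int] = {}
    tops: dict[str, dict[int, list[str]]] = {}
    for name, sub in (("cr", cr_set), ("common", full_set)):
        if len(sub) == 0:
            return {c: 0 for c in components}
        dm = build_dosage(sub)
        scaled, _, _, _ = scale_center(dm.values.T)
        if scaled.shape[1] == 0:
            return {c: 0 for c in components}
        res = pca(scaled)
        avail = [c for c in components if c <= res.n_components]
        tops[name] = rank_informative(res, components=avail, k=k)
    for c in components:
        a = set(tops["cr"].get(c, ()))
        b = set(tops["common"].get(c, ()))
        out[c] = len(a & b)
    return out


def evaluate_reference(
    table: VariantTable,
    coverage: Mapping[str, IntervalSet],
    thresholds: FilterThresholds | None = None,
    reference_id: str = "reference",
) -> ReferenceEvalReport:
    """Category counts (each predicate on the full set, independently),
    shared-region statistics, and TOP100 strategy concordance."""
    thresholds = thresholds or FilterThresholds()
    n = len(table.samples)
    shared = intersect_coverage(list(coverage.values())) if coverage else IntervalSet()

    indel_multi = sum(1 for r in table if r.site_class() != "biallelic_snv")
    low_depth = sum(
        1 for r in table
        if any(
            c is not None and not c.is_missing
            and (c.dp is None or c.dp <= thresholds.min_depth_exclusive)
            for c in (r.calls.get(s) for s in table.samples)
        )
    )
    qual_fail = sum(1 for r in table if quality_fail(r, thresholds.min_site_quality))

    def is_fixed(r) -> bool:
        fracs = [f for f in r.alt_fractions(table.samples) if f is not None]
        if not fracs:
            return False
        return all(f >= thresholds.t_high for f in fracs) or all(
            f <= thresholds.t_low for f in fracs
        )

    fixed = sum(1 for r in table if is_fixed(r))
    common = sum(
        1 for r in table
        if r.call_rate(n) == 1.0 and shared.contains_point(r.contig, r.pos - 1)
    )
    cr_pass = sum(1 for r in table if r.call_rate(n) >= thresholds.min_cr)

    return ReferenceEvalReport(
        reference_id=reference_id,
        total_variants=len(table),
        indel_multiallelic=indel_multi,
        low_depth=low_depth,
        quality_fail_count=qual_fail,
        fixed=fixed,
        common_among_species=common,
        cr_pass=cr_pass,
        top_concordance=_top100_concordance(table, thresholds),
        overlap=overlap_stats(shared),
    )


#: criterion name -> (attribute getter, higher_is_better)
_CRITERIA = {
    "fixed": (lambda r: r.fixed, False),
    "common_among_species": (lambda r: r.common_among_species, True),
    "mean_overlap_length": (
        lambda r: (r.overlap.mean_length if r.overlap and r.overlap.mean_length
                   is not None else 0.0),
        True,
    ),
    "top_concordance": (lambda r: r.top_concordance_total, True),
}


def rank_references(reports: Sequence[ReferenceEvalReport]) -> pd.DataFrame:
    """Per-criterion rank matrix (1 = best) plus a mean-rank ordering.

    Fewer fixed variants, more common variants, longer mean shared regions
    and higher TOP100 concordance all rank better.  No scalar winner is
    forced; the mean rank is one reading of the matrix, reported alongside
    the per-criterion ranks.
    """
    if not reports:
        raise ValueError("need at least one report")
    idx = [r.reference_id for r in reports]
    ranks = pd.DataFrame(index=idx, dtype=float)
    for name, (get, higher_better) in _CRITERIA.items():
        vals = pd.Series([get(r) for r in reports], index=idx, dtype=float)
        ranks[name] = vals.rank(ascending=not higher_better, method="min")
    ranks["mean_rank"] = ranks.mean(axis=1)
    return ranks.sort_values("mean_rank")
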