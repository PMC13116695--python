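"""Variant records and multi-sample tables.

A :class:`VariantRecord` is one called site with per-sample depth (DP),
allele depths (AD), genotype quality (GQ) and a possibly-missing genotype.
Samples here are pooled libraries (50 individuals each), so per-sample AD
fractions estimate population allele frequencies rather than a diploid
genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = ["SampleCall", "VariantRecord", "VariantTable", "read_vcf"]

MISSING = "."


@dataclass(frozen=True)
class SampleCall:
    """Per-sample fields at one site. ``ad`` is read count per allele (ref first)."""

    dp: int | None
    ad: tuple[int, ...] | None
    gq: int | None
    genotype: str | None  # e.g. "0/1"; None = missing call

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    def alt_fraction(self) -> float | None:
        """Alt-allele read fraction alt/(ref+alt); None when uninformative.

        Defined for biallelic AD only; a missing genotype or zero informative
        depth makes the sample missing at this site.
        """
        if self.is_missing or self.ad is None or len(self.ad) < 2:
            return None
        ref, alt = self.ad[0], self.ad[1]
        total = ref + alt
        if total <= 0:
            return None
        return alt / total


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    pos: int  # 1-based, as in VCF
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    calls: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or any(not a for a in self.alts):
            raise ValueError(f"empty allele string at {self.contig}:{self.pos}")

    @property
    def variant_id(self) -> str:
        return f"{self.contig}_{self.pos}"

    def site_class(self) -> str:
        """One of biallelic_snv | indel | multiallelic."""
        if len(self.alts) > 1:
            return "multiallelic"
        if len(self.ref) == 1 and len(self.alts[0]) == 1:
            return "biallelic_snv"
        return "indel"

    def call_rate(self, n_samples: int | None = None) -> float:
        if n_samples is None:
            n_samples = len(self.calls)
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        called = sum(1 for c in self.calls.values() if not c.is_missing)
        return called / n_samples

    def alt_fractions(self, samples: Sequence[str]) -> list[float | None]:
        return [
            self.calls[s].alt_fraction() if s in self.calls else None for s in samples
        ]


@dataclass
class VariantTable:
    """Ordered collection of records over a fixed sample list."""

    samples: list[str]
    records: list[VariantRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def subset(self, keep: Iterable[VariantRecord]) -> "VariantTable":
        keep = list(keep)
        return VariantTable(samples=list(self.samples), records=keep)

    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Site-level summary with per-sample alt fractions (NaN = missing)."""
        rows = []
        for r in self.records:
            row: dict = {
                "variant_id": r.variant_id,
                "contig": r.contig,
                "pos": r.pos,
                "ref": r.ref,
                "alt": ",".join(r.alts),
                "qual": r.qual,
                "site_class": r.site_class(),
            }
            for s, f in zip(self.samples, r.alt_fractions(self.samples)):
                row[f"freq_{s}"] = np.nan if f is None else f
            rows.append(row)
        return pd.DataFrame(rows)

    def write_vcf(self, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
        """Write a minimal VCF v4.2 with GT:DP:AD:GQ sample fields."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if contig_lengths:
                for contig, length in contig_lengths.items():
                    fh.write(f"##contig=<ID={contig},length={length}>\n")
            else:
                for contig in dict.fromkeys(r.contig for r in self.records):
                    fh.write(f"##contig=<ID={contig}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (Phred, capped at 127)">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for r in self.records:
                qual = "." if r.qual is None else f"{r.qual:g}"
                fields = [
                    r.contig, str(r.pos), r.variant_id, r.ref, ",".join(r.alts),
                    qual, "PASS", ".", "GT:DP:AD:GQ",
                ]
                for s in self.samples:
                    c = r.calls.get(s)
                    if c is None or c.is_missing:
                        gt = "./."
                    else:
                        gt = c.genotype
                    dp = MISSING if c is None or c.dp is None else str(c.dp)
                    ad = MISSING if c is None or c.ad is None else ",".join(map(str, c.ad))
                    gq = MISSING if c is None or c.gq is None else str(c.gq)
                    fields.append(f"{gt}:{dp}:{ad}:{gq}")
                fh.write("\t".join(fields) + "\n")


def _gt_string(gt: tuple) -> str | None:
    if gt is None or all(a is None for a in gt):
        return None
    return "/".join("." if a is None else str(a) for a in gt)


def read_vcf(path: str | Path) -> VariantTable:
    """Load a multi-sample VCF (plain or bgzipped) into a :class:`VariantTable`."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf.fetch() if vf.index is not None else vf:
            calls: dict[str, SampleCall] = {}
            for s in samples:
                sc = rec.samples[s]
                gt = _gt_string(sc.get("GT"))
                dp = sc.get("DP")
                ad = sc.get("AD")
                gq = sc.get("GQ")
                calls[s] = SampleCall(
                    dp=None if dp is None else int(dp),
                    ad=None if ad is None or all(a is None for a in ad)
                    else tuple(int(a) for a in ad),
                    gq=None if gq is None else int(gq),
                    genotype=gt,
                )
            alts = tuple(rec.alts) if rec.alts else ()
            if not alts:
                continue  # monomorphic line; not a variant
            qual = None if rec.qual is None or math.isnan(rec.qual) else float(rec.qual)
            records.append(
                VariantRecord(
                    contig=rec.contig, pos=rec.pos, ref=rec.ref,
                    alts=alts, qual=qual, calls=calls,
                )
            )
    return VariantTable(samples=samples, records=records)
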