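"""Flanking-sequence extraction around diagnostic SNPs for probe design.

Each candidate carries 50 bp of reference sequence on each side of the
SNP (truncated and flagged at contig ends), a cleanliness flag (no other
variant and no N in either flank) and, per side, the longest variant-free
stretch adjacent to the SNP — primer-binding regions of 18–25 bp free of
variation are the working requirement, so the default minimum clear run
is 25 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .model import DiagnosticCall
from .variants import VariantTable

__all__ = ["ProbeCandidate", "extract_flanks", "candidates_to_fasta"]


@dataclass
class ProbeCandidate:
    variant_id: str
    contig: str
    pos: int  # 1-based SNP position
    ref_allele: str
    alt_allele: str
    left_flank: str
    right_flank: str
    clean: bool
    clear_left: int  # variant-free bp adjacent to the SNP, left side
    clear_right: int
    truncated: bool
    min_clear: int

    @property
    def passes_clear(self) -> bool:
        return min(self.clear_left, self.clear_right) >= self.min_clear

    @property
    def sequence(self) -> str:
        """left flank + reference allele + right flank."""
        return self.left_flank + self.ref_allele + self.right_flank

    def fasta_header(self) -> str:
        return (f"{self.variant_id} pos={self.pos} ref={self.ref_allele} "
                f"alt={self.alt_allele} clean={str(self.clean).lower()} "
                f"clear={self.clear_left},{self.clear_right} "
                f"truncated={str(self.truncated).lower()}")


def extract_flanks(
    calls: Sequence[DiagnosticCall],
    reference: Mapping[str, str],
    all_variants: VariantTable | None = None,
    flank: int = 50,
    min_clear: int = 25,
) -> list[ProbeCandidate]:
    """Reference flanks around each called SNP, annotated for cleanliness.

    ``all_variants`` supplies the positions of *every* called site (not just
    the panel) so nearby variation inside a flank is detected; the SNP's own
    site never counts against itself.
    """
    # variant positions per contig, for clear-run computation
    positions: dict[str, list[int]] = {}
    if all_variants is not None:
        for r in all_variants:
            positions.setdefault(r.contig, []).append(r.pos)

    by_id: dict[str, tuple[str, int, str, str]] = {}
    if all_variants is not None:
        for r in all_variants:
            by_id[r.variant_id] = (r.contig, r.pos, r.ref, r.alts[0])

    out: list[ProbeCandidate] = []
    for call in calls:
        if call.variant_id in by_id:
            contig, pos, ref_allele, alt_allele = by_id[call.variant_id]
        else:
            contig, _, pos_s = call.variant_id.rpartition("_")
            pos = int(pos_s)
            ref_allele = alt_allele = "N"
        seq = reference.get(contig)
        if seq is None:
            raise ValueError(f"reference lacks contig {contig!r}")
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"{call.variant_id}: position outside contig")
        pos0 = pos - 1
        if ref_allele != "N":
            ref_allele = seq[pos0]  # SNP: reference base at the site
        left_start = max(0, pos0 - flank)
        left = seq[left_start:pos0]
        right = seq[pos0 + 1: pos0 + 1 + flank]
        truncated = len(left) < flank or len(right) < flank

        near = [p for p in positions.get(contig, ()) if p != pos]
        left_hits = [pos - p for p in near if 0 < pos - p <= len(left)]
        right_hits = [p - pos for p in near if 0 < p - pos <= len(right)]
        clear_left = min(left_hits) - 1 if left_hits else len(left)
        clear_right = min(right_hits) - 1 if right_hits else len(right)
        clean = (
            not left_hits and not right_hits
            and "N" not in left.upper() and "N" not in right.upper()
        )
        out.append(ProbeCandidate(
            variant_id=call.variant_id, contig=contig, pos=pos,
            ref_allele=ref_allele, alt_allele=alt_allele,
            left_flank=left, right_flank=right, clean=clean,
            clear_left=clear_left, clear_right=clear_right,
            truncated=truncated, min_clear=min_clear,
        ))
    return out


def candidates_to_frame(candidates: Sequence[ProbeCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variant_id": c.variant_id, "contig": c.contig, "pos": c.pos,
        "ref": c.ref_allele, "alt": c.alt_allele,
        "left_flank": c.left_flank, "right_flank": c.right_flank,
        "clean": c.clean, "clear_left": c.clear_left, "clear_right": c.clear_right,
        "passes_clear": c.passes_clear, "truncated": c.truncated,
    } for c in candidates])


def candidates_to_fasta(candidates: Sequence[ProbeCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.fasta_header()}\n{c.sequence}\n")
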