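"""Packaged in-study allele-frequency fixtures.

Two small frequency matrices over the four target species — *Palmistichus
elaeisis* (PA03), *Trichospilus diatraeae* (TD01), *Trichogramma pretiosum*
(TP02) and *Tetrastichus howardi* (TH04, sequenced in duplicate) — shipped
as TSV data files: 15 published species-specific variants and 12 pairwise
differentiation variants, with their genotype qualities and published call
labels.  These are the worked-example substrate for the diagnostic rules,
PCA and distance analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dosage import DosageMatrix

__all__ = [
    "SPECIES",
    "SAMPLES",
    "SAMPLE_SPECIES",
    "load_table4",
    "load_table5",
    "combined_frequencies",
    "combined_dosage",
]

SPECIES = ["PA03", "TD01", "TP02", "TH04"]
#: sample (replicate) ids; TH04 was sequenced twice
SAMPLES = ["PA03", "TD01", "TP02", "TH04", "TH04_2"]
SAMPLE_SPECIES = {"PA03": "PA03", "TD01": "TD01", "TP02": "TP02",
                  "TH04": "TH04", "TH04_2": "TH04"}

_FREQ_COLS = ["freq_PA03", "freq_TD01", "freq_TP02", "freq_TH04", "freq_TH04.1"]
_GQ_COLS = ["gq_PA03", "gq_TD01", "gq_TP02", "gq_TH04", "gq_TH04.1"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("diagsnp.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", index_col="variant_id")


def load_table4() -> pd.DataFrame:
    """15 species-specific variants: frequencies, GQ, published target label."""
    return _load("table4_specific.tsv")


def load_table5() -> pd.DataFrame:
    """12 pairwise variants: frequencies, GQ, published Low/High pair labels."""
    return _load("table5_pairwise.tsv")


def _freqs(table: pd.DataFrame) -> pd.DataFrame:
    out = table[_FREQ_COLS].copy()
    out.columns = SAMPLES
    return out


def combined_frequencies() -> pd.DataFrame:
    """All 27 fixture variants × 5 replicate samples (alt-allele frequency)."""
    return pd.concat([_freqs(load_table4()), _freqs(load_table5())])


def combined_dosage() -> DosageMatrix:
    return DosageMatrix(values=combined_frequencies(), species=dict(SAMPLE_SPECIES))


def gq_matrix() -> pd.DataFrame:
    """Genotype qualities for the 27 fixture variants (carried to reports)."""
    out = pd.concat([load_table4()[_GQ_COLS], load_table5()[_GQ_COLS]])
    out.columns = SAMPLES
    return out
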