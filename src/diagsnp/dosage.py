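"""Allele-proportion (dosage) matrices.

The substrate for PCA, distances and the diagnostic rules: a variants ×
samples matrix of alt-allele read proportions in [0, 1], with missing
values where a sample had no informative depth or no genotype call.
The complement ``1 - f`` is the reference-allele dosage; every analysis
in the package is invariant (or label-swapped) under that complement, so
storing the alt proportion is a recorded convention, not a modelling
choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import VariantTable

__all__ = ["DosageMatrix", "build_dosage", "scale_center"]


@dataclass
class DosageMatrix:
    """Variants × samples allele proportions with species labels.

    ``values``: DataFrame indexed by variant id, one column per sample,
    NaN = missing.  ``species``: sample id → species label.
    """

    values: pd.DataFrame
    species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        finite = self.values.to_numpy(dtype=float)
        bad = (finite < 0) | (finite > 1)
        if np.nansum(bad):
            raise ValueError("dosage values must lie in [0, 1]")
        for s in self.values.columns:
            self.species.setdefault(s, s)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def species_of(self, sample: str) -> str:
        return self.species[sample]

    def samples_by_species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            out.setdefault(self.species[s], []).append(s)
        return out

    def species_means(self) -> pd.DataFrame:
        """Variants × species matrix, replicate samples averaged."""
        groups = self.samples_by_species()
        return pd.DataFrame(
            {sp: self.values[cols].mean(axis=1) for sp, cols in groups.items()}
        )

    def complement(self) -> "DosageMatrix":
        return DosageMatrix(values=1.0 - self.values, species=dict(self.species))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="variant_id")


def build_dosage(
    table: VariantTable, manifest: pd.DataFrame | dict[str, str] | None = None
) -> DosageMatrix:
    """Dosage matrix from a filtered variant table.

    ``manifest`` maps sample id → species (DataFrame with ``sample_id`` and
    ``species`` columns, or a plain dict); by default each sample is its own
    species.  Raises if the manifest names a sample absent from the table.
    """
    if len(table) == 0:
        raise ValueError("variant table is empty")
    if manifest is None:
        species = {s: s for s in table.samples}
    elif isinstance(manifest, dict):
        species = dict(manifest)
    else:
        species = dict(zip(manifest["sample_id"], manifest["species"]))
    unknown = [s for s in species if s not in table.samples]
    if unknown:
        raise ValueError(f"manifest samples absent from VCF: {', '.join(unknown)}")

    data = {
        r.variant_id: [
            np.nan if f is None else f for f in r.alt_fractions(table.samples)
        ]
        for r in table
    }
    values = pd.DataFrame.from_dict(
        data, orient="index", columns=table.samples
    )
    return DosageMatrix(values=values, species={s: species.get(s, s) for s in table.samples})


def scale_center(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], pd.Series, pd.Series]:
    """Center and unit-scale variant columns of a samples × variants matrix.

    Missing values are excluded from the moments and imputed to 0 after
    centering (the column mean).  Zero-variance columns are dropped and
    reported.  Returns ``(scaled, dropped, means, sds)``; the moments are
    kept so that new samples can be projected with the training statistics.
    """
    means = matrix.mean(axis=0, skipna=True)
    sds = matrix.std(axis=0, ddof=1, skipna=True)
    keep = sds.index[(sds > 0) & sds.notna()]
    dropped = [c for c in matrix.columns if c not in set(keep)]
    centered = matrix[keep].sub(means[keep], axis=1).div(sds[keep], axis=1)
    return centered.fillna(0.0), dropped, means[keep], sds[keep]
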