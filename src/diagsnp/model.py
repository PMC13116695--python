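"""Diagnostic marker selection: PCA, ranking, diagnostic rules, distances.

The central objects follow the model/results pattern:

* :class:`DiagnosticPanel` — built from a :class:`~diagsnp.dosage.DosageMatrix`
  (or a DataFrame / filtered VCF); holds the data and the replicate → species
  mapping.
* :class:`PanelResults` — returned by :meth:`DiagnosticPanel.fit`; carries the
  species-specific and pairwise diagnostic calls, the PCA of the centered and
  scaled species matrix, Euclidean distances with a clustering leaf order, and
  a ``summary()`` table.  Simulation and classification hang off this object.

The diagnostic rules label each species LOW (every replicate's alt-allele
frequency <= t_low), HIGH (every replicate >= t_high) or AMBIGUOUS.  A
species-specific call needs no AMBIGUOUS species and exactly one species
alone on its side of the threshold; a pairwise call needs a clean
two-against-two split.  The two call sets are disjoint by construction
(1-vs-3 versus 2-vs-2 splits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .dosage import DosageMatrix, build_dosage, scale_center
from .variants import VariantTable, read_vcf

__all__ = [
    "PCAResult",
    "DiagnosticCall",
    "pca",
    "rank_informative",
    "label_sides",
    "call_species_specific",
    "call_pairwise",
    "euclidean_matrix",
    "DiagnosticPanel",
    "PanelResults",
]

LOW, HIGH, AMBIGUOUS = "LOW", "HIGH", "AMBIGUOUS"


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    """Principal components of a samples × variants matrix.

    ``scores``: samples × components; ``loadings``: variants × components;
    ``variance_ratio`` sums to 1 over the retained (nonzero) components.
    ``means``/``sds`` are the training centering/scaling statistics, kept so
    new samples can be projected consistently.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_ratio: np.ndarray
    means: pd.Series
    sds: pd.Series

    @property
    def n_components(self) -> int:
        return len(self.variance_ratio)

    def project(self, samples: pd.DataFrame) -> pd.DataFrame:
        """Project new samples (rows × the training variants) into PC space.

        Columns are centered and scaled with the TRAINING statistics before
        multiplication into the loading basis; missing values are imputed to
        the training mean.  An all-missing sample is rejected.
        """
        missing_cols = [c for c in self.means.index if c not in samples.columns]
        if missing_cols:
            raise ValueError(
                f"samples lack {len(missing_cols)} training variants "
                f"(e.g. {missing_cols[0]})"
            )
        X = samples[self.means.index]
        all_missing = X.isna().all(axis=1)
        if all_missing.any():
            raise ValueError(
                f"sample(s) with no observed dosages: "
                f"{', '.join(map(str, X.index[all_missing]))}"
            )
        scaled = X.sub(self.means, axis=1).div(self.sds, axis=1).fillna(0.0)
        coords = scaled.to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(coords, index=samples.index, columns=self.loadings.columns)


def pca(scaled: pd.DataFrame, means: pd.Series | None = None,
        sds: pd.Series | None = None) -> PCAResult:
    """SVD-based principal components of an already centered+scaled matrix.

    Variance proportions are singular values squared over their total, so
    the nonzero components (at most n_samples − 1 after centering) sum to 1.
    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive.
    """
    if scaled.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if scaled.shape[1] < 1:
        raise ValueError("PCA needs at least 1 variant")
    X = scaled.to_numpy(dtype=float)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > s[0] * 1e-10 if s[0] > 0 else s > 0
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(len(s)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    names = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(U * s, index=scaled.index, columns=names)
    loadings = pd.DataFrame(Vt.T, index=scaled.columns, columns=names)
    variance_ratio = s**2 / np.sum(s**2)
    if means is None:
        means = pd.Series(0.0, index=scaled.columns)
    if sds is None:
        sds = pd.Series(1.0, index=scaled.columns)
    return PCAResult(scores=scores, loadings=loadings,
                     variance_ratio=variance_ratio, means=means, sds=sds)


def _tiebreak_key(variant_id: str) -> tuple[str, int]:
    contig, _, pos = str(variant_id).rpartition("_")
    try:
        return (contig, int(pos))
    except ValueError:
        return (str(variant_id), 0)


def rank_informative(
    result: PCAResult, components: Sequence[int] = (1, 2, 3), k: int = 100
) -> dict[int, list[str]]:
    """Top-k variants per component by absolute loading, descending.

    Ties are broken by (contig, position) ascending.  ``components`` are
    1-based (PC1 = 1).  ``k`` larger than the variant count returns all.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    out: dict[int, list[str]] = {}
    for c in components:
        if not (1 <= c <= result.n_components):
            raise ValueError(
                f"component {c} out of range 1..{result.n_components}"
            )
        col = result.loadings[f"PC{c}"]
        order = sorted(
            col.index, key=lambda v: (-abs(col[v]),) + _tiebreak_key(v)
        )
        out[c] = order[:k]
    return out


# ---------------------------------------------------------------------------
# Diagnostic rules

@dataclass(frozen=True)
class DiagnosticCall:
    """A variant labeled species-specific or pairwise, with thresholds used."""

    variant_id: str
    call_type: str  # "species_specific" | "pairwise"
    target: str | tuple[tuple[str, str], tuple[str, str]]
    t_low: float
    t_high: float
    side_labels: Mapping[str, str] = field(default_factory=dict)

    @property
    def low_pair(self) -> tuple[str, str] | None:
        return self.target[0] if self.call_type == "pairwise" else None

    @property
    def high_pair(self) -> tuple[str, str] | None:
        return self.target[1] if self.call_type == "pairwise" else None


def label_sides(
    values: pd.DataFrame, species_map: Mapping[str, str],
    t_low: float = 0.1, t_high: float = 0.9,
) -> pd.DataFrame:
    """Per-variant, per-species LOW/HIGH/AMBIGUOUS labels.

    ``values`` is variants × replicate columns; ``species_map`` assigns each
    column to a species.  A species is LOW only if every non-missing
    replicate is <= t_low (HIGH analogously, >= t_high); disagreement among
    replicates, intermediate values or an all-missing species are AMBIGUOUS.
    """
    unknown = [c for c in values.columns if c not in species_map]
    if unknown:
        raise ValueError(f"columns with no species label: {', '.join(map(str, unknown))}")
    species = list(dict.fromkeys(species_map[c] for c in values.columns))
    out = pd.DataFrame(index=values.index, columns=species, dtype=object)
    for sp in species:
        cols = [c for c in values.columns if species_map[c] == sp]
        sub = values[cols]
        n_obs = sub.notna().sum(axis=1)
        low = sub.le(t_low).where(sub.notna()).all(axis=1) & (n_obs > 0)
        high = sub.ge(t_high).where(sub.notna()).all(axis=1) & (n_obs > 0)
        lab = np.where(low, LOW, np.where(high, HIGH, AMBIGUOUS))
        out[sp] = lab
    return out


def call_species_specific(
    values: pd.DataFrame, species_map: Mapping[str, str],
    t_low: float = 0.1, t_high: float = 0.9,
) -> list[DiagnosticCall]:
    """Variants where exactly one species sits alone on its threshold side."""
    labels = label_sides(values, species_map, t_low, t_high)
    calls: list[DiagnosticCall] = []
    for vid, row in labels.iterrows():
        if (row == AMBIGUOUS).any():
            continue
        low = [sp for sp in labels.columns if row[sp] == LOW]
        high = [sp for sp in labels.columns if row[sp] == HIGH]
        lone: str | None = None
        if len(low) == 1 and len(high) == len(labels.columns) - 1:
            lone = low[0]
        elif len(high) == 1 and len(low) == len(labels.columns) - 1:
            lone = high[0]
        if lone is not None:
            calls.append(DiagnosticCall(
                variant_id=str(vid), call_type="species_specific", target=lone,
                t_low=t_low, t_high=t_high, side_labels=dict(row),
            ))
    return calls


def call_pairwise(
    values: pd.DataFrame, species_map: Mapping[str, str],
    t_low: float = 0.1, t_high: float = 0.9,
) -> list[DiagnosticCall]:
    """Variants splitting the species into a low pair and a high pair."""
    labels = label_sides(values, species_map, t_low, t_high)
    calls: list[DiagnosticCall] = []
    for vid, row in labels.iterrows():
        if (row == AMBIGUOUS).any():
            continue
        low = tuple(sorted(sp for sp in labels.columns if row[sp] == LOW))
        high = tuple(sorted(sp for sp in labels.columns if row[sp] == HIGH))
        if len(low) == 2 and len(high) == 2:
            calls.append(DiagnosticCall(
                variant_id=str(vid), call_type="pairwise", target=(low, high),
                t_low=t_low, t_high=t_high, side_labels=dict(row),
            ))
    return calls


def calls_to_frame(calls: Sequence[DiagnosticCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        if c.call_type == "species_specific":
            rows.append({"variant_id": c.variant_id, "call_type": c.call_type,
                         "specific": c.target, "low": "", "high": "",
                         "t_low": c.t_low, "t_high": c.t_high})
        else:
            rows.append({
                "variant_id": c.variant_id, "call_type": c.call_type, "specific": "",
                "low": " x ".join(c.low_pair), "high": " x ".join(c.high_pair),
                "t_low": c.t_low, "t_high": c.t_high,
            })
    return pd.DataFrame(
        rows, columns=["variant_id", "call_type", "specific", "low", "high",
                       "t_low", "t_high"],
    )


# ---------------------------------------------------------------------------
# Distances

def euclidean_matrix(scaled: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Euclidean distances between sample rows, plus a dendrogram
    leaf order from complete-linkage hierarchical clustering."""
    if scaled.shape[0] < 2:
        raise ValueError("distance matrix needs at least 2 samples")
    condensed = pdist(scaled.to_numpy(dtype=float), metric="euclidean")
    dm = pd.DataFrame(squareform(condensed), index=scaled.index, columns=scaled.index)
    order = [scaled.index[i] for i in leaves_list(linkage(condensed, method="complete"))]
    return dm, order


# ---------------------------------------------------------------------------
# Model / Results

class DiagnosticPanel:
    """Marker-selection model over a dosage matrix with species labels.

    Parameters
    ----------
    dosage:
        Variants × samples allele proportions with a sample → species map.
        Replicate samples of one species are kept as separate columns; the
        diagnostic rules demand replicate agreement, while PCA and distances
        use the per-species replicate mean.
    """

    def __init__(self, dosage: DosageMatrix):
        self.dosage = dosage

    # -- constructors -------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, species: Mapping[str, str] | None = None
    ) -> "DiagnosticPanel":
        species = dict(species) if species else {c: c for c in values.columns}
        return cls(DosageMatrix(values=values.copy(), species=species))

    @classmethod
    def from_variant_table(
        cls, table: VariantTable, manifest: pd.DataFrame | dict | None = None
    ) -> "DiagnosticPanel":
        return cls(build_dosage(table, manifest))

    @classmethod
    def from_vcf(
        cls, vcf_path: str | Path, manifest: pd.DataFrame | dict | None = None
    ) -> "DiagnosticPanel":
        return cls.from_variant_table(read_vcf(vcf_path), manifest)

    # -- fitting ------------------------------------------------------
    def fit(self, t_low: float = 0.1, t_high: float = 0.9) -> "PanelResults":
        if not (0.0 <= t_low < t_high <= 1.0):
            raise ValueError(f"need 0 <= t_low < t_high <= 1, got {t_low}, {t_high}")
        values = self.dosage.values
        species_map = self.dosage.species
        specific = call_species_specific(values, species_map, t_low, t_high)
        pairwise = call_pairwise(values, species_map, t_low, t_high)

        species_matrix = self.dosage.species_means().T  # species × variants
        scaled, dropped, means, sds = scale_center(species_matrix)
        pca_result = pca(scaled, means=means, sds=sds) if scaled.shape[1] else None
        distances, leaf_order = (
            euclidean_matrix(scaled) if scaled.shape[1] else (None, None)
        )
        return PanelResults(
            panel=self, t_low=t_low, t_high=t_high,
            specific_calls=specific, pairwise_calls=pairwise,
            pca=pca_result, scaled=scaled, dropped_variants=dropped,
            distances=distances, cluster_order=leaf_order,
        )


@dataclass
class PanelResults:
    """Fitted diagnostic panel: calls, PCA, distances, summary."""

    panel: DiagnosticPanel
    t_low: float
    t_high: float
    specific_calls: list[DiagnosticCall]
    pairwise_calls: list[DiagnosticCall]
    pca: PCAResult | None
    scaled: pd.DataFrame
    dropped_variants: list[str]
    distances: pd.DataFrame | None
    cluster_order: list[str] | None

    @property
    def calls(self) -> list[DiagnosticCall]:
        return list(self.specific_calls) + list(self.pairwise_calls)

    @property
    def panel_variant_ids(self) -> list[str]:
        return [c.variant_id for c in self.calls]

    def calls_frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)

    def specific_counts(self) -> pd.Series:
        species = list(dict.fromkeys(self.panel.dosage.species.values()))
        counts = pd.Series(0, index=species, dtype=int)
        for c in self.specific_calls:
            counts[c.target] += 1
        return counts

    def rank_informative(
        self, components: Sequence[int] = (1, 2, 3), k: int = 100
    ) -> dict[int, list[str]]:
        if self.pca is None:
            raise ValueError("no PCA available (all variant columns dropped)")
        return rank_informative(self.pca, components=components, k=k)

    def species_profiles(self) -> pd.DataFrame:
        """Per-species dosage profiles (replicates averaged), variants × species."""
        return self.panel.dosage.species_means()

    def summary(self) -> str:
        n_var = len(self.panel.dosage.variant_ids)
        lines = [
            "Diagnostic panel summary",
            "========================",
            f"variants analysed:        {n_var}",
            f"samples (replicates):     {len(self.panel.dosage.sample_ids)}",
            f"species:                  "
            f"{', '.join(dict.fromkeys(self.panel.dosage.species.values()))}",
            f"thresholds:               t_low={self.t_low}  t_high={self.t_high}",
            f"species-specific calls:   {len(self.specific_calls)}",
            f"pairwise calls:           {len(self.pairwise_calls)}",
            f"panel size (union):       {len(self.calls)}",
        ]
        counts = self.specific_counts()
        lines.append("specific calls per species: "
                     + ", ".join(f"{sp}={int(n)}" for sp, n in counts.items()))
        if self.pca is not None:
            pct = ", ".join(
                f"PC{i + 1}={100 * v:.2f}%" for i, v in enumerate(self.pca.variance_ratio)
            )
            lines.append(f"PCA variance explained:   {pct}")
        if self.distances is not None:
            off = self.distances.where(
                ~np.eye(len(self.distances), dtype=bool)
            )
            pair = off.stack().idxmin()
            lines.append(
                f"closest species pair:     {pair[0]}–{pair[1]} "
                f"(d={off.stack().min():.3f})"
            )
        return "\n".join(lines)
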