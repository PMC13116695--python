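"""In-silico pure replicates and pairwise species mixtures.

Samples are simulated on dosage vectors, not reads: a pure sample
replicates one species' allele-proportion profile; a mixture is the convex
combination ``p·A + (1−p)·B`` per variant.  With four species, 15
replicates per species gives 60 pure samples, and all six unordered pairs
at proportions {0.25, 0.5, 0.75} give 18 mixed samples — the study design.

``noise="binomial"`` resamples every dosage as ``Binomial(depth, f)/depth``
at the configured depth (default 30×); ``noise="noiseless"`` copies the
convex combination exactly, which is the mode the exact-property
invariants (convexity, label symmetry, midpoint projection) hold in.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MixtureSample", "simulate_pure", "simulate_mixtures", "samples_to_frame"]


@dataclass
class MixtureSample:
    """A simulated profile tagged with parent species and mixing proportion."""

    sample_id: str
    parents: tuple[str, ...]  # one species (pure) or an ordered pair
    proportion: float  # share of the first parent
    dosage: pd.Series
    seed: int | None = None

    @property
    def is_pure(self) -> bool:
        return len(self.parents) == 1 or self.proportion in (0.0, 1.0)

    @property
    def majority_parent(self) -> str | None:
        """Parent contributing > 50%; None for an exact 50–50 mixture."""
        if len(self.parents) == 1:
            return self.parents[0]
        if self.proportion > 0.5:
            return self.parents[0]
        if self.proportion < 0.5:
            return self.parents[1]
        return None

    @property
    def label(self) -> str:
        if len(self.parents) == 1:
            return self.parents[0]
        return f"{self.parents[0]}x{self.parents[1]}_{int(round(self.proportion * 100))}"


def _apply_noise(
    dosage: pd.Series, noise: str, depth: int, rng: np.random.Generator
) -> pd.Series:
    if noise == "noiseless":
        return dosage.copy()
    if noise == "binomial":
        vals = dosage.to_numpy(dtype=float)
        out = np.full_like(vals, np.nan)
        ok = ~np.isnan(vals)
        out[ok] = rng.binomial(depth, vals[ok]) / depth
        return pd.Series(out, index=dosage.index)
    raise ValueError(f"unknown noise mode {noise!r}")


def simulate_pure(
    profiles: pd.DataFrame,
    n_per_species: int = 15,
    noise: str = "noiseless",
    depth: int = 30,
    seed: int = 0,
) -> list[MixtureSample]:
    """``n_per_species`` replicate samples of each species profile.

    ``profiles`` is variants × species.  The default 15 replicates of four
    species yields the study's 60 pure samples.
    """
    if n_per_species < 0:
        raise ValueError("n_per_species must be >= 0")
    if profiles.shape[1] == 0:
        raise ValueError("profiles has no species")
    rng = np.random.default_rng(seed)
    out: list[MixtureSample] = []
    for sp in profiles.columns:
        for i in range(n_per_species):
            out.append(MixtureSample(
                sample_id=f"{sp}_pure_{i + 1}", parents=(str(sp),), proportion=1.0,
                dosage=_apply_noise(profiles[sp], noise, depth, rng), seed=seed,
            ))
    return out


def simulate_mixtures(
    profiles: pd.DataFrame,
    proportions: Sequence[float] = (0.25, 0.5, 0.75),
    pairs: Sequence[tuple[str, str]] | None = None,
    noise: str = "noiseless",
    depth: int = 30,
    seed: int = 0,
) -> list[MixtureSample]:
    """One sample per (unordered species pair, proportion of the first parent).

    Four species × proportions {0.25, 0.5, 0.75} → 6 pairs × 3 = 18 samples.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 species to mix")
    for p in proportions:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"proportion {p} outside [0, 1]")
    if pairs is None:
        pairs = list(itertools.combinations(profiles.columns, 2))
    rng = np.random.default_rng(seed)
    out: list[MixtureSample] = []
    for a, b in pairs:
        for p in proportions:
            mixed = p * profiles[str(a)] + (1.0 - p) * profiles[str(b)]
            out.append(MixtureSample(
                sample_id=f"{a}x{b}_{int(round(p * 100))}",
                parents=(str(a), str(b)), proportion=float(p),
                dosage=_apply_noise(mixed, noise, depth, rng), seed=seed,
            ))
    return out


def samples_to_frame(samples: Sequence[MixtureSample]) -> pd.DataFrame:
    """Samples × variants dosage table with parent/proportion metadata columns."""
    meta = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "parent_a": [s.parents[0] for s in samples],
        "parent_b": [s.parents[1] if len(s.parents) > 1 else "" for s in samples],
        "proportion": [s.proportion for s in samples],
    }).set_index("sample_id")
    dosages = pd.DataFrame(
        {s.sample_id: s.dosage for s in samples}
    ).T
    dosages.index.name = "sample_id"
    return meta.join(dosages)
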