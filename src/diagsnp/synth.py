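"""Synthetic pooled-sequencing scenarios with planted truth.

Generates a reference contig, per-species pooled allele-frequency profiles
with planted variant categories (species-specific, pairwise, fixed,
low-depth, indel, multiallelic, edge-proximal, missing-call), per-sample
coverage intervals with deliberate gaps, a multi-sample VCF with GT:DP:AD:GQ
fields, raw reads, and a machine-readable truth table.  Every downstream
stage of the pipeline is testable against the truth table without any
external data.

Two noise modes are provided.  ``noiseless`` sets each sample's alt read
count to ``round(freq * depth)`` — the natural model for replicated pooled
profiles — while ``binomial`` draws ``alt ~ Binomial(depth, freq)`` for
robustness experiments.  All randomness flows from the explicit scenario
seed; identical configurations are byte-identical on disk.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .variants import SampleCall, VariantRecord, VariantTable

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "CapacityError",
    "generate_reference",
    "plant_variants",
    "emit_vcf",
    "generate_reads",
    "simulate_scenario",
    "gq_from_allele_depths",
]

BASES = np.array(["A", "C", "G", "T"])
DEFAULT_SPECIES = ["PA03", "TD01", "TP02", "TH04"]
GQ_CAP = 127
READ_ERROR = 1e-3

# geometry of planted sites: >= 50 bp margins, sites far enough apart that
# the 20 bp flank window of one never touches another
SITE_MARGIN = 60
SITE_SPACING = 101
GAP_LENGTH = 30
EDGE_OFFSET = 6  # gap starts this many bases right of an edge-proximal site


class CapacityError(ValueError):
    """Genome too small for the requested planted-variant counts."""


@dataclass
class ScenarioConfig:
    """Scenario parameters: species, planted counts, depth and read geometry."""

    n_species: int = 4
    species: list[str] | None = None
    replicates: dict[str, int] | None = None  # default 1 per species
    genome_length: int = 20_000
    n_specific_per_species: int = 2
    n_pairwise_per_pair: int = 1
    n_fixed: int = 2
    n_low_depth: int = 2
    n_indel: int = 2
    n_multiallelic: int = 2
    n_edge_proximal: int = 2
    n_missing_call: int = 2
    mean_depth: int = 30
    read_length: int = 150
    noise: str = "noiseless"  # or "binomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species is None:
            if self.n_species == 4:
                self.species = list(DEFAULT_SPECIES)
            else:
                self.species = [f"SP{i + 1:02d}" for i in range(self.n_species)]
        if len(self.species) != self.n_species:
            raise ValueError("species list length must equal n_species")
        if self.replicates is None:
            self.replicates = {s: 1 for s in self.species}
        for s in self.species:
            self.replicates.setdefault(s, 1)
        counts = [
            self.n_specific_per_species, self.n_pairwise_per_pair, self.n_fixed,
            self.n_low_depth, self.n_indel, self.n_multiallelic,
            self.n_edge_proximal, self.n_missing_call,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("planted-variant counts must be >= 0")
        if self.mean_depth < 1 or self.read_length < 1 or self.genome_length < 1:
            raise ValueError("mean_depth, read_length and genome_length must be >= 1")
        if self.noise not in ("noiseless", "binomial"):
            raise ValueError(f"unknown noise mode {self.noise!r}")

    @property
    def sample_names(self) -> list[str]:
        names = []
        for s in self.species:
            reps = self.replicates[s]
            names.append(s)
            names.extend(f"{s}_{r}" for r in range(2, reps + 1))
        return names

    @property
    def sample_species(self) -> dict[str, str]:
        return {name: name.split("_")[0] for name in self.sample_names}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def generate_reference(length: int, seed: int, contig_id: str = "chrS1") -> tuple[str, str]:
    """Uniform-composition reference contig; returns (contig_id, sequence)."""
    if length < 1:
        raise ValueError(f"reference length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return contig_id, "".join(rng.choice(BASES, size=length))


def _pair_partitions(species: list[str]) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """All (low_pair, high_pair) ordered splits of the species into 2+2."""
    out = []
    for low in itertools.combinations(species, 2):
        high = tuple(s for s in species if s not in low)
        if len(high) == 2:
            out.append((low, high))
    return out


def plant_variants(
    ref: tuple[str, str], cfg: ScenarioConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign positions, categories and true per-species allele frequencies.

    Returns ``(truth, profiles)``: the truth table (one row per planted
    variant) and the variants-by-species matrix of true alt-allele
    frequencies.  Species-specific sites put exactly one species on the
    minority side of the 0.1/0.9 thresholds; pairwise sites split the
    species two-against-two; the remaining categories are designed to be
    removed by their designated filtering stage.
    """
    contig_id, seq = ref
    species = cfg.species
    n_pairwise_total = 0
    pair_splits: list[tuple[tuple[str, str], tuple[str, str]]] = []
    if cfg.n_pairwise_per_pair > 0:
        if len(species) != 4:
            raise ValueError("pairwise planting requires exactly 4 species")
        pair_splits = _pair_partitions(species)
        n_pairwise_total = cfg.n_pairwise_per_pair * len(pair_splits)

    n_total = (
        cfg.n_specific_per_species * len(species)
        + n_pairwise_total
        + cfg.n_fixed + cfg.n_low_depth + cfg.n_indel
        + cfg.n_multiallelic + cfg.n_edge_proximal + cfg.n_missing_call
    )
    # reserve 110 bp at the 3' end so decoy coverage gaps never touch a
    # planted site's flank window
    usable = len(seq) - SITE_MARGIN - max(SITE_MARGIN, 110)
    max_slots = usable // SITE_SPACING + 1 if usable >= 0 else 0
    if n_total > max_slots:
        raise CapacityError(
            f"genome of {len(seq)} bp holds at most {max_slots} planted sites "
            f"(margin {SITE_MARGIN}, spacing {SITE_SPACING}); requested {n_total}"
        )

    positions = [SITE_MARGIN + i * SITE_SPACING + 1 for i in range(n_total)]  # 1-based
    rows: list[dict] = []
    slot = 0

    def base_freqs(value_for: dict[str, float], default: float) -> dict[str, float]:
        return {s: value_for.get(s, default) for s in species}

    # species-specific: alternate the minority side per index; odd-indexed
    # sites get a near-threshold target frequency (0.03 / 0.97) so the
    # profiles carry the not-quite-fixed values real pooled data shows
    for s in species:
        for i in range(cfg.n_specific_per_species):
            if i % 2 == 0:
                freqs = base_freqs({s: 0.0 if i % 4 == 0 else 0.03}, 1.0)
            else:
                freqs = base_freqs({s: 1.0 if i % 4 == 1 else 0.97}, 0.0)
            rows.append(dict(category="specific", target=s, pos=positions[slot], **{
                f"freq_{k}": v for k, v in freqs.items()}))
            slot += 1

    for j, (low, high) in enumerate(pair_splits):
        for i in range(cfg.n_pairwise_per_pair):
            freqs = {s: (0.0 if s in low else 1.0) for s in species}
            if (j + i) % 2 == 1:
                freqs[low[0]] = 0.03
                freqs[high[0]] = 0.97
            rows.append(dict(
                category="pairwise", target=f"{low[0]}|{low[1]}x{high[0]}|{high[1]}",
                pos=positions[slot], **{f"freq_{k}": v for k, v in freqs.items()}))
            slot += 1

    for _ in range(cfg.n_fixed):
        rows.append(dict(category="fixed", target="", pos=positions[slot],
                         **{f"freq_{s}": 1.0 for s in species}))
        slot += 1
    for i in range(cfg.n_low_depth):
        s = species[i % len(species)]
        freqs = base_freqs({s: 0.0}, 1.0)
        rows.append(dict(category="low_depth", target=s, pos=positions[slot],
                         **{f"freq_{k}": v for k, v in freqs.items()}))
        slot += 1
    for i in range(cfg.n_indel):
        s = species[i % len(species)]
        freqs = base_freqs({s: 0.0}, 1.0)
        rows.append(dict(category="indel", target=s, pos=positions[slot],
                         **{f"freq_{k}": v for k, v in freqs.items()}))
        slot += 1
    for i in range(cfg.n_multiallelic):
        s = species[i % len(species)]
        freqs = base_freqs({s: 0.0}, 1.0)
        rows.append(dict(category="multiallelic", target=s, pos=positions[slot],
                         **{f"freq_{k}": v for k, v in freqs.items()}))
        slot += 1
    for i in range(cfg.n_edge_proximal):
        s = species[i % len(species)]
        freqs = base_freqs({s: 0.0}, 1.0)
        rows.append(dict(category="edge", target=s, pos=positions[slot],
                         **{f"freq_{k}": v for k, v in freqs.items()}))
        slot += 1
    for i in range(cfg.n_missing_call):
        # the single genotyped sample carries an intermediate frequency so the
        # site reaches the call-rate stage before being removed there
        keep = cfg.sample_names[i % len(cfg.sample_names)]
        freqs = {s: 0.5 for s in species}
        rows.append(dict(category="missing", target=keep, pos=positions[slot],
                         **{f"freq_{k}": v for k, v in freqs.items()}))
        slot += 1

    truth = pd.DataFrame(
        rows, columns=["category", "target", "pos"] + [f"freq_{s}" for s in species]
    )
    truth.insert(0, "contig", contig_id)
    truth.insert(1, "variant_id", [f"{contig_id}_{p}" for p in truth["pos"]])
    profiles = truth.set_index("variant_id")[[f"freq_{s}" for s in species]]
    profiles.columns = species
    return truth, profiles


def gq_from_allele_depths(dp: int, alt: int, error: float = READ_ERROR) -> int:
    """Phred genotype quality from pooled allele depths, capped at 127.

    Posterior over the three canonical pool-frequency classes {0, 1/2, 1}
    (flat prior, per-read error ``error``); GQ = −10·log10(1 − max posterior).
    """
    if dp <= 0:
        return 0
    ps = np.array([error, 0.5, 1.0 - error])
    loglik = alt * np.log(ps) + (dp - alt) * np.log1p(-ps)
    loglik -= loglik.max()
    post = np.exp(loglik)
    post /= post.sum()
    p_err = 1.0 - post.max()
    if p_err <= 10 ** (-GQ_CAP / 10):
        return GQ_CAP
    return min(GQ_CAP, int(round(-10.0 * math.log10(p_err))))


def _genotype_from_fraction(f: float) -> str:
    if f <= 0.1:
        return "0/0"
    if f >= 0.9:
        return "1/1"
    return "0/1"


def _alt_base(ref_base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != ref_base]
    return choices[int(rng.integers(len(choices)))]


def emit_vcf(
    truth: pd.DataFrame, ref: tuple[str, str], cfg: ScenarioConfig
) -> tuple[VariantTable, dict[str, IntervalSet]]:
    """Materialize the truth table as a VariantTable plus per-sample coverage.

    Allele depths follow the configured noise mode; GQ is the capped Phred
    score from :func:`gq_from_allele_depths`.  Coverage is the whole contig
    minus a 30 bp gap just right of every edge-proximal site (with
    a deterministic per-sample 1 bp stagger) and two decoy gaps near the 3'
    end, keeping every sample above 95% covered.
    """
    contig_id, seq = ref
    L = len(seq)
    rng = np.random.default_rng(cfg.seed + 1)
    samples = cfg.sample_names
    sample_species = cfg.sample_species

    bad = truth[truth["pos"] > L]
    if len(bad):
        raise ValueError(
            f"planted position {int(bad['pos'].iloc[0])} exceeds contig length {L}"
        )

    # coverage: gaps right of edge sites, staggered 1 bp per sample index
    edge_gaps = [
        (int(pos) - 1 + EDGE_OFFSET, int(pos) - 1 + EDGE_OFFSET + GAP_LENGTH)
        for pos in truth.loc[truth["category"] == "edge", "pos"]
    ]
    decoy_gaps = [(L - 45, L - 25), (L - 15, L - 5)] if L >= 120 else []
    coverage: dict[str, IntervalSet] = {}
    for k, name in enumerate(samples):
        gaps = sorted(
            [(max(0, g0 - k), g1) for g0, g1 in edge_gaps] + decoy_gaps
        )
        ivs = []
        cursor = 0
        for g0, g1 in gaps:
            if g0 > cursor:
                ivs.append((cursor, g0))
            cursor = max(cursor, g1)
        if cursor < L:
            ivs.append((cursor, L))
        coverage[name] = IntervalSet({contig_id: ivs})

    records: list[VariantRecord] = []
    for row in truth.itertuples(index=False):
        pos = int(row.pos)
        pos0 = pos - 1
        ref_base = seq[pos0]
        category = row.category
        if category == "indel":
            ref_allele = seq[pos0: pos0 + 2]
            alts = (ref_allele[0],)  # 2 bp -> 1 bp deletion
        elif category == "multiallelic":
            a1 = _alt_base(ref_base, rng)
            a2 = _alt_base(ref_base, rng)
            while a2 == a1:
                a2 = _alt_base(ref_base, rng)
            ref_allele, alts = ref_base, (a1, a2)
        else:
            ref_allele, alts = ref_base, (_alt_base(ref_base, rng),)

        calls: dict[str, SampleCall] = {}
        for name in samples:
            freq = float(getattr(row, f"freq_{sample_species[name]}"))
            dp = cfg.mean_depth
            if category == "low_depth" and name == samples[0]:
                dp = 8  # fails DP > 10 in this sample
            if cfg.noise == "binomial":
                alt_n = int(rng.binomial(dp, freq))
            else:
                alt_n = int(round(freq * dp))
            if category == "multiallelic":
                # split alt reads across the two alt alleles
                a1n = alt_n // 2
                ad = (dp - alt_n, a1n, alt_n - a1n)
            else:
                ad = (dp - alt_n, alt_n)
            frac = alt_n / dp if dp else 0.0
            genotype: str | None = _genotype_from_fraction(frac)
            if category == "multiallelic" and frac > 0.1:
                genotype = "1/2"
            if category == "missing" and name != row.target:
                genotype = None
            calls[name] = SampleCall(
                dp=dp, ad=ad, gq=gq_from_allele_depths(dp, alt_n), genotype=genotype
            )
        records.append(
            VariantRecord(
                contig=contig_id, pos=pos, ref=ref_allele, alts=alts,
                qual=60.0, calls=calls,
            )
        )
    return VariantTable(samples=samples, records=records), coverage


def generate_reads(
    ref: tuple[str, str], n_reads: int, read_length: int, seed: int
) -> list[tuple[str, str, str]]:
    """Uniformly-placed single-end reads as (id, bases, quality) triples."""
    if n_reads < 0:
        raise ValueError(f"n_reads must be >= 0, got {n_reads}")
    contig_id, seq = ref
    if read_length > len(seq):
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(seq) - read_length + 1, size=n_reads)
    quals = rng.integers(30, 41, size=(n_reads, read_length))
    out = []
    for i, s in enumerate(starts):
        bases = seq[s: s + read_length]
        q = "".join(chr(33 + int(v)) for v in quals[i])
        out.append((f"read_{i}_{contig_id}_{s}", bases, q))
    return out


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, bases, qual in reads:
            fh.write(f"@{rid}\n{bases}\n+\n{qual}\n")


@dataclass
class Scenario:
    """In-memory bundle of one synthetic scenario."""

    config: ScenarioConfig
    reference: tuple[str, str]
    truth: pd.DataFrame
    profiles: pd.DataFrame
    variants: VariantTable
    coverage: dict[str, IntervalSet] = field(default_factory=dict)

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.config.sample_names,
             "species": [self.config.sample_species[s] for s in self.config.sample_names]}
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA / VCF / BEDs / truth / manifest; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        contig_id, seq = self.reference
        paths: dict[str, Path] = {}
        fasta = outdir / "reference.fa"
        with open(fasta, "w") as fh:
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")
        paths["reference"] = fasta
        vcf = outdir / "variants.vcf"
        self.variants.write_vcf(vcf, contig_lengths={contig_id: len(seq)})
        paths["vcf"] = vcf
        for name, ivset in self.coverage.items():
            bed = outdir / f"coverage_{name}.bed"
            ivset.write_bed(bed)
            paths[f"coverage_{name}"] = bed
        truth_tsv = outdir / "truth.tsv"
        self.truth.to_csv(truth_tsv, sep="\t", index=False)
        paths["truth"] = truth_tsv
        truth_json = outdir / "truth.json"
        truth_json.write_text(json.dumps(self.truth.to_dict(orient="records"), indent=2))
        paths["truth_json"] = truth_json
        manifest = outdir / "manifest.tsv"
        self.manifest.to_csv(manifest, sep="\t", index=False)
        paths["manifest"] = manifest
        return paths


def simulate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Run reference generation, variant planting and VCF emission end to end."""
    ref = generate_reference(cfg.genome_length, cfg.seed)
    truth, profiles = plant_variants(ref, cfg)
    table, coverage = emit_vcf(truth, ref, cfg)
    return Scenario(
        config=cfg, reference=ref, truth=truth, profiles=profiles,
        variants=table, coverage=coverage,
    )
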