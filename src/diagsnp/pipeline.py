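"""End-to-end orchestration: config, stage execution, consolidated report.

`run_pipeline` drives simulate (optional) → qc (optional) → filter →
refeval → markers → mix → classify → probes over either a synthetic
scenario or user-supplied VCF/BED/FASTA inputs, embedding every stage's
report — with seeds and a full parameter echo — in a single JSON document.
Reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .classify import evaluate, train
from .dosage import build_dosage
from .filtering import FilterThresholds, run_cascade
from .intervals import IntervalSet
from .mixtures import samples_to_frame, simulate_mixtures, simulate_pure
from .model import DiagnosticPanel
from .probes import candidates_to_fasta, candidates_to_frame, extract_flanks
from .qc import run_fastq_qc
from .refeval import evaluate_reference
from .synth import ScenarioConfig, Scenario, simulate_scenario
from .variants import read_vcf

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every stage threshold with its default, plus input/output paths.

    When ``vcf`` is unset a synthetic scenario is simulated with
    ``scenario`` (or its defaults) and used as the pipeline input.
    """

    # inputs (all optional; simulate fills the gaps)
    vcf: str | None = None
    coverage_beds: dict[str, str] | None = None  # sample -> BED path
    reference_fasta: str | None = None
    manifest: str | None = None
    fastq_in: str | None = None

    # qc
    head_trim: int = 10
    min_len: int = 50
    # filtering
    min_dp: int = 10
    window: int = 20
    t_low: float = 0.1
    t_high: float = 0.9
    min_cr: float = 0.5
    # probes
    flank: int = 50
    min_clear: int = 25
    # mixtures / classification
    proportions: tuple[float, ...] = (0.25, 0.5, 0.75)
    n_pure_per_species: int = 15
    depth: int = 30
    mixture_noise: str = "noiseless"

    seed: int = 0
    out_dir: str = "diagsnp_out"
    scenario: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0.0 <= self.t_low < self.t_high <= 1.0):
            raise ValueError(
                f"need 0 <= t_low < t_high <= 1, got t_low={self.t_low}, "
                f"t_high={self.t_high}"
            )
        if self.head_trim < 0 or self.min_len < 0:
            raise ValueError("head_trim and min_len must be >= 0")
        if self.window < 0 or self.flank < 1:
            raise ValueError("window must be >= 0 and flank >= 1")
        for p in self.proportions:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"proportion {p} outside [0, 1]")
        if self.n_pure_per_species < 0 or self.depth < 1:
            raise ValueError("n_pure_per_species >= 0 and depth >= 1 required")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "proportions" in data:
            data["proportions"] = tuple(data["proportions"])
        return cls(**data)

    def to_json(self) -> str:
        d = asdict(self)
        d["proportions"] = list(self.proportions)
        return json.dumps(d, indent=2, sort_keys=True)

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            min_depth_exclusive=self.min_dp, window=self.window,
            t_low=self.t_low, t_high=self.t_high, min_cr=self.min_cr,
        )


def _log(msg: str) -> None:
    # human-readable progress on stderr only; machine outputs stay on stdout/files
    sys.stderr.write(f"[diagsnp {time.strftime('%H:%M:%S')}] {msg}\n")


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the consolidated report (also written
    to ``<out_dir>/report.json`` together with every stage output)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "diagsnp",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "stages": {},
    }

    # -- simulate ------------------------------------------------------
    scenario: Scenario | None = None
    if config.vcf is None:
        _log("simulate: generating synthetic scenario")
        scfg = ScenarioConfig(**{**config.scenario, "seed": config.seed})
        scenario = simulate_scenario(scfg)
        paths = scenario.write(out / "scenario")
        table = scenario.variants
        coverage = scenario.coverage
        reference = {scenario.reference[0]: scenario.reference[1]}
        manifest = dict(zip(scenario.manifest["sample_id"], scenario.manifest["species"]))
        report["stages"]["simulate"] = {
            "config": json.loads(scfg.to_json()),
            "n_planted": len(scenario.truth),
            "outputs": {k: str(v) for k, v in paths.items()},
        }
    else:
        _log(f"load: {config.vcf}")
        table = read_vcf(config.vcf)
        coverage = {
            s: IntervalSet.read_bed(p) for s, p in (config.coverage_beds or {}).items()
        }
        reference = _read_fasta(config.reference_fasta) if config.reference_fasta else None
        manifest = None
        if config.manifest:
            import pandas as pd

            mf = pd.read_csv(config.manifest, sep="\t")
            manifest = dict(zip(mf["sample_id"], mf["species"]))
        report["stages"]["simulate"] = {"skipped": True}

    # -- qc (optional) -------------------------------------------------
    if config.fastq_in:
        _log("qc: trimming and filtering reads")
        qc_report = run_fastq_qc(
            config.fastq_in, out / "reads.qc.fastq",
            head_trim=config.head_trim, min_length=config.min_len,
            report_path=out / "qc_report.json",
        )
        report["stages"]["qc"] = json.loads(qc_report.to_json())
    else:
        report["stages"]["qc"] = {"skipped": True}

    # -- filter --------------------------------------------------------
    _log("filter: running variant-retention cascade")
    thresholds = config.thresholds()
    retained, filter_report = run_cascade(table, coverage, thresholds, reference)
    retained.write_vcf(out / "filtered.vcf")
    filter_report.write(out / "filter_report.json")
    report["stages"]["filter"] = json.loads(filter_report.to_json())

    # -- refeval -------------------------------------------------------
    _log("refeval: reference evaluation metrics")
    ref_report = evaluate_reference(
        table, coverage, thresholds,
        reference_id=Path(config.vcf).stem if config.vcf else "synthetic",
    )
    (out / "refeval.json").write_text(ref_report.to_json())
    report["stages"]["refeval"] = json.loads(ref_report.to_json())

    # -- markers -------------------------------------------------------
    _log("markers: dosage, PCA, diagnostic rules, distances")
    if len(retained) == 0:
        report["stages"]["markers"] = {"n_calls": 0, "note": "no variants retained"}
        report["stages"]["mix"] = {"skipped": True}
        report["stages"]["classify"] = {"skipped": True}
        report["stages"]["probes"] = {"skipped": True}
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report
    panel = DiagnosticPanel.from_variant_table(retained, manifest)
    results = panel.fit(t_low=config.t_low, t_high=config.t_high)
    results.calls_frame().to_csv(out / "diagnostic_calls.tsv", sep="\t", index=False)
    panel.dosage.to_tsv(out / "dosage.tsv")
    if results.pca is not None:
        results.pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        results.pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    if results.distances is not None:
        results.distances.to_csv(out / "distances.tsv", sep="\t")
    report["stages"]["markers"] = {
        "n_specific": len(results.specific_calls),
        "n_pairwise": len(results.pairwise_calls),
        "panel_size": len(results.calls),
        "specific_counts": {k: int(v) for k, v in results.specific_counts().items()},
        "variance_ratio": (
            [float(v) for v in results.pca.variance_ratio]
            if results.pca is not None else None
        ),
    }

    # -- mix -----------------------------------------------------------
    _log("mix: simulating pure and mixed samples")
    profiles = results.species_profiles()
    pure = simulate_pure(
        profiles, n_per_species=config.n_pure_per_species,
        noise=config.mixture_noise, depth=config.depth, seed=config.seed,
    )
    mixed = simulate_mixtures(
        profiles, proportions=config.proportions,
        noise=config.mixture_noise, depth=config.depth, seed=config.seed + 1,
    )
    samples_to_frame(pure + mixed).to_csv(out / "simulated_samples.tsv", sep="\t")
    report["stages"]["mix"] = {"n_pure": len(pure), "n_mixed": len(mixed)}

    # -- classify --------------------------------------------------------
    _log("classify: SVM validation")
    if profiles.shape[1] >= 2 and config.n_pure_per_species > 0:
        model = train(pure, seed=config.seed)
        model.save(out / "classifier.json")
        clf_report = evaluate(model, pure + mixed)
        (out / "classifier_report.json").write_text(clf_report.to_json())
        report["stages"]["classify"] = {
            "accuracy_pure": clf_report.accuracy_pure,
            "accuracy_mixed": clf_report.accuracy_mixed,
            "per_proportion": {str(k): v for k, v in clf_report.per_proportion.items()},
        }
    else:
        report["stages"]["classify"] = {"skipped": True}

    # -- probes ----------------------------------------------------------
    if reference is not None:
        _log("probes: extracting flanking sequence")
        candidates = extract_flanks(
            results.calls, reference, all_variants=table,
            flank=config.flank, min_clear=config.min_clear,
        )
        candidates_to_frame(candidates).to_csv(out / "probes.tsv", sep="\t", index=False)
        candidates_to_fasta(candidates, out / "probes.fa")
        report["stages"]["probes"] = {
            "n_candidates": len(candidates),
            "n_clean": sum(c.clean for c in candidates),
            "n_pass_clear": sum(c.passes_clear for c in candidates),
        }
    else:
        report["stages"]["probes"] = {"skipped": True, "reason": "no reference sequence"}

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _log("done")
    return report
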