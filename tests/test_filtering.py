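"""Variant-retention cascade: stage predicates, ordering, truth recovery."""

import numpy as np
import pytest

from diagsnp.filtering import (
    FilterThresholds,
    call_rate_filter,
    depth_filter,
    fixed_filter,
    flank_filter,
    run_cascade,
    site_class_filter,
)
from diagsnp.intervals import IntervalSet
from diagsnp.synth import ScenarioConfig, simulate_scenario
from diagsnp.variants import SampleCall, VariantRecord, VariantTable

SAMPLES = ["S1", "S2", "S3", "S4"]


def make_record(pos=100, ref="A", alts=("G",), qual=60.0, dp=(30,) * 4,
                frac=(0.5,) * 4, missing=(), contig="c"):
    calls = {}
    for s, d, f in zip(SAMPLES, dp, frac):
        alt_n = round(f * d)
        calls[s] = SampleCall(
            dp=d, ad=(d - alt_n, alt_n), gq=99,
            genotype=None if s in missing else "0/1",
        )
    return VariantRecord(contig=contig, pos=pos, ref=ref, alts=tuple(alts),
                         qual=qual, calls=calls)


def table(*records):
    return VariantTable(samples=SAMPLES, records=list(records))


class TestSiteClass:
    @pytest.mark.parametrize("ref,alts,expected", [
        ("A", ("G",), "biallelic_snv"),
        ("A", ("G", "T"), "multiallelic"),
        ("AT", ("A",), "indel"),
        ("A", ("AT",), "indel"),
    ])
    def test_classification(self, ref, alts, expected):
        assert make_record(ref=ref, alts=alts).site_class() == expected

    def test_empty_allele_rejected(self):
        with pytest.raises(ValueError):
            make_record(ref="", alts=("G",))


class TestDepth:
    def test_all_above_threshold_retained(self):
        t = table(make_record(dp=(30, 30, 30, 30)))
        assert len(depth_filter(t)) == 1

    def test_dp_exactly_10_fails_strict_comparison(self):
        t = table(make_record(dp=(30, 10, 30, 30)))
        assert len(depth_filter(t)) == 0
        assert len(depth_filter(table(make_record(dp=(30, 11, 30, 30))))) == 1

    def test_missing_samples_not_evaluated(self):
        t = table(make_record(dp=(30, 5, 30, 30), missing=("S2",)))
        assert len(depth_filter(t)) == 1

    def test_empty_table(self):
        assert len(depth_filter(table())) == 0


class TestCallRate:
    def test_half_called_retained_inclusive(self):
        t = table(make_record(missing=("S3", "S4")))  # CR = 0.5
        assert len(call_rate_filter(t, 0.5)) == 1

    def test_quarter_called_removed(self):
        t = table(make_record(missing=("S2", "S3", "S4")))  # CR = 0.25
        assert len(call_rate_filter(t, 0.5)) == 0

    def test_fully_called_retained(self):
        assert len(call_rate_filter(table(make_record()), 0.5)) == 1

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            VariantTable(samples=[], records=[]).records or call_rate_filter(
                VariantTable(samples=[], records=[make_record()]), 0.5
            )


class TestFixed:
    @pytest.mark.parametrize("frac,kept", [
        ((1, 1, 1, 1), False),          # fixed high
        ((1, 0, 1, 1), True),           # diagnostic pattern
        ((0.05, 0.02, 0.0, 0.08), False),  # fixed low
        ((0.5, 0.5, 0.5, 0.5), True),
    ])
    def test_patterns(self, frac, kept):
        t = table(make_record(frac=frac))
        assert (len(fixed_filter(t)) == 1) is kept

    def test_no_informative_depth_removed(self):
        rec = make_record()
        rec = VariantRecord(
            contig=rec.contig, pos=rec.pos, ref=rec.ref, alts=rec.alts,
            qual=rec.qual,
            calls={s: SampleCall(dp=0, ad=(0, 0), gq=0, genotype="0/0")
                   for s in SAMPLES},
        )
        assert len(fixed_filter(table(rec))) == 0


def brute_force_flank(t, coverage, window, reference=None):
    """Per-base reimplementation of the flank rule (oracle for small genomes)."""
    kept = []
    for r in t:
        pos0 = r.pos - 1
        ok = True
        for ivset in coverage.values():
            base_ok = np.zeros(10_000, dtype=bool)
            for contig, a, b in ivset.iter_intervals():
                if contig == r.contig:
                    base_ok[a:b] = True
            for p in range(pos0 - window, pos0 + window + 1):
                if p < 0 or not base_ok[p]:
                    ok = False
        for other in t:
            if other is not r and other.contig == r.contig and \
                    abs(other.pos - r.pos) <= window:
                ok = False
        if reference is not None and ok:
            seq = reference.get(r.contig, "")
            sub = seq[max(0, pos0 - window): pos0 + window + 1]
            if "N" in sub:
                ok = False
        if ok:
            kept.append(r.variant_id)
    return kept


class TestFlank:
    def cov(self, *pairs):
        return {s: IntervalSet({"c": list(pairs)}) for s in SAMPLES}

    def test_variant_near_gap_removed(self):
        # coverage ends 5 bp right of the site
        t = table(make_record(pos=100, frac=(1, 0, 1, 1)))
        out = flank_filter(t, self.cov((0, 104)), window=20)
        assert len(out) == 0

    def test_variant_well_inside_coverage_retained(self):
        t = table(make_record(pos=100, frac=(1, 0, 1, 1)))
        assert len(flank_filter(t, self.cov((0, 500)), window=20)) == 1

    def test_close_neighbors_mutually_removed(self):
        t = table(make_record(pos=100), make_record(pos=110))
        assert len(flank_filter(t, self.cov((0, 500)), window=20)) == 0

    def test_n_in_reference_window_removes(self):
        t = table(make_record(pos=100))
        ref = {"c": "A" * 90 + "N" + "A" * 409}
        assert len(flank_filter(t, self.cov((0, 500)), window=20, reference=ref)) == 0
        ref_clean = {"c": "A" * 500}
        assert len(flank_filter(t, self.cov((0, 500)), window=20,
                                reference=ref_clean)) == 1

    def test_uncovered_contig_removed(self):
        t = table(make_record(pos=100, contig="other"))
        assert len(flank_filter(t, self.cov((0, 500)), window=20)) == 0

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            positions = sorted(rng.choice(np.arange(30, 2000), size=8, replace=False))
            records = [make_record(pos=int(p)) for p in positions]
            t = table(*records)
            cuts = sorted(rng.choice(np.arange(0, 2100), size=4, replace=False))
            pairs = [(int(cuts[0]), int(cuts[1])), (int(cuts[2]), int(cuts[3]))]
            coverage = {s: IntervalSet({"c": pairs}) for s in SAMPLES}
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=2100))
            ref = {"c": seq}
            window = int(rng.integers(0, 30))
            got = flank_filter(t, coverage, window, ref).variant_ids()
            assert got == brute_force_flank(t, coverage, window, ref)


class TestCascade:
    def test_noiseless_scenario_recovers_planted_panel(self, scenario):
        ref = {scenario.reference[0]: scenario.reference[1]}
        retained, report = run_cascade(
            scenario.variants, scenario.coverage, FilterThresholds(), ref
        )
        want = set(
            scenario.truth.loc[
                scenario.truth["category"].isin(["specific", "pairwise"]),
                "variant_id",
            ]
        )
        assert set(retained.variant_ids()) == want

    def test_each_planted_category_removed_at_designated_stage(self, scenario):
        ref = {scenario.reference[0]: scenario.reference[1]}
        _, report = run_cascade(
            scenario.variants, scenario.coverage, FilterThresholds(), ref
        )
        removed = {s["stage"]: s["n_removed"] for s in report.stages}
        cfg = scenario.config
        assert removed["site_class"] == cfg.n_indel + cfg.n_multiallelic
        assert removed["depth"] == cfg.n_low_depth
        assert removed["fixed"] == cfg.n_fixed
        assert removed["flank"] == cfg.n_edge_proximal
        assert removed["call_rate"] == cfg.n_missing_call

    def test_report_reconciles_and_chains(self, scenario):
        _, report = run_cascade(scenario.variants, scenario.coverage)
        for stage in report.stages:
            assert stage["n_out"] == stage["n_in"] - stage["n_removed"]
        for a, b in zip(report.stages, report.stages[1:]):
            assert a["n_out"] == b["n_in"]
        assert report.stages[0]["n_in"] == len(scenario.variants)

    def test_monotone_cascade_on_random_scenarios(self):
        for seed in range(12):
            cfg = ScenarioConfig(seed=seed, noise="binomial", genome_length=6000,
                                 n_specific_per_species=1, n_pairwise_per_pair=0,
                                 n_fixed=1, n_low_depth=1, n_indel=1,
                                 n_multiallelic=1, n_edge_proximal=1,
                                 n_missing_call=1)
            sc = simulate_scenario(cfg)
            _, report = run_cascade(sc.variants, sc.coverage)
            outs = [s["n_out"] for s in report.stages]
            ins = [s["n_in"] for s in report.stages]
            assert all(o <= i for o, i in zip(outs, ins))

    def test_all_indel_input_removed_at_first_stage(self):
        t = table(*[make_record(pos=100 + 50 * i, ref="AT", alts=("A",))
                    for i in range(3)])
        retained, report = run_cascade(t, {s: IntervalSet({"c": [(0, 500)]})
                                           for s in SAMPLES})
        assert len(retained) == 0
        assert report.stages[0]["n_removed"] == 3

    def test_relaxed_thresholds_leave_only_site_class_binding(self):
        records = [
            make_record(pos=100, frac=(0.3, 0.6, 0.4, 0.7), dp=(5, 30, 8, 2)),
            make_record(pos=110, frac=(0.2, 0.8, 0.5, 0.5), missing=("S1", "S2", "S3")),
            make_record(pos=130, ref="AT", alts=("A",)),
            make_record(pos=150, alts=("G", "T")),
        ]
        t = table(*records)
        thresholds = FilterThresholds(min_depth_exclusive=-1, window=0,
                                      t_low=0.0, t_high=1.0, min_cr=0.0)
        retained, _ = run_cascade(t, {s: IntervalSet({"c": [(90, 200)]})
                                      for s in SAMPLES}, thresholds)
        assert set(retained.variant_ids()) == {"c_100", "c_110"}

    def test_depth_and_site_class_stages_commute(self, scenario):
        t = scenario.variants
        a = depth_filter(site_class_filter(t))
        b = site_class_filter(depth_filter(t))
        assert a.variant_ids() == b.variant_ids()

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(t_low=0.9, t_high=0.1).validate()
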