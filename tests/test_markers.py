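"""Dosage matrix, PCA, diagnostic rules, distances on the fixture panel."""

import numpy as np
import pandas as pd
import pytest

from diagsnp import fixtures
from diagsnp.dosage import DosageMatrix, build_dosage, scale_center
from diagsnp.model import (
    DiagnosticPanel,
    call_pairwise,
    call_species_specific,
    euclidean_matrix,
    pca,
    rank_informative,
)
from diagsnp.variants import SampleCall, VariantRecord, VariantTable

SP_MAP = dict(fixtures.SAMPLE_SPECIES)


def freq_frame(rows: dict[str, tuple]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=fixtures.SAMPLES)


class TestBuildDosage:
    def make_table(self):
        calls_a = {"S1": SampleCall(30, (0, 30), 99, "1/1"),
                   "S2": SampleCall(30, (15, 15), 99, "0/1")}
        rec = VariantRecord(contig="c", pos=100, ref="A", alts=("G",),
                            qual=60.0, calls=calls_a)
        return VariantTable(samples=["S1", "S2"], records=[rec])

    def test_alt_fraction_values(self):
        dm = build_dosage(self.make_table())
        assert dm.values.loc["c_100", "S1"] == 1.0
        assert dm.values.loc["c_100", "S2"] == 0.5

    def test_unknown_manifest_sample_rejected(self):
        with pytest.raises(ValueError, match="S9"):
            build_dosage(self.make_table(), {"S9": "X"})

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            build_dosage(VariantTable(samples=["S1"], records=[]))

    def test_published_frequency_row_reconstructed(self, table4):
        # the TP02-specific variant with frequencies (0.05, 0.016, 1, 0, 0)
        row = fixtures.combined_frequencies().loc["CM037085.1_14072991"]
        assert list(row) == [0.05, 0.016, 1.0, 0.0, 0.0]

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            DosageMatrix(values=pd.DataFrame({"S1": [1.2]}, index=["v1"]))


class TestScaleCenter:
    def test_columns_standardized(self):
        m = pd.DataFrame({"v1": [1.0, 0.0, 1.0, 1.0], "v2": [0.2, 0.4, 0.9, 0.1]})
        scaled, dropped, means, sds = scale_center(m)
        assert dropped == []
        assert np.allclose(scaled.mean(axis=0), 0.0)
        assert np.allclose(scaled.std(axis=0, ddof=1), 1.0)

    def test_constant_column_dropped(self):
        m = pd.DataFrame({"v1": [1.0, 1.0, 1.0], "v2": [0.0, 0.5, 1.0]})
        scaled, dropped, _, _ = scale_center(m)
        assert dropped == ["v1"]
        assert list(scaled.columns) == ["v2"]

    def test_missing_values_imputed_to_zero_after_centering(self):
        m = pd.DataFrame({"v1": [1.0, np.nan, 0.0, 0.5]})
        scaled, _, means, _ = scale_center(m)
        assert scaled.iloc[1, 0] == 0.0
        assert means["v1"] == pytest.approx(0.5)

    def test_empty_matrix_passthrough(self):
        scaled, dropped, _, _ = scale_center(pd.DataFrame(index=[0, 1]))
        assert scaled.shape[1] == 0 and dropped == []


class TestPCA:
    def test_rank_bound_and_variance_sums_to_one(self, fixture_results):
        res = fixture_results.pca
        assert res.n_components == 3  # 4 species rows -> at most 3
        assert res.variance_ratio.sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.random((8, 6)))
        scaled, _, _, _ = scale_center(X)
        res = pca(scaled)
        # oracle: eigenvalues of the sample covariance of the scaled matrix
        S = np.cov(scaled.to_numpy(), rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(S))[::-1]
        n = scaled.shape[0]
        sv_var = res.variance_ratio * (scaled.to_numpy() ** 2).sum() / (n - 1)
        assert np.allclose(sv_var, eig[: len(sv_var)], atol=1e-8)
        assert np.allclose(
            res.variance_ratio, eig[: len(sv_var)] / eig.sum(), atol=1e-8
        )

    def test_duplicated_sample_rows_keep_variance_proportions(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.random((5, 7)))
        base = pca(scale_center(X)[0])
        dup = pd.concat([X, X], ignore_index=True)
        doubled = pca(scale_center(dup)[0])
        assert np.allclose(
            base.variance_ratio, doubled.variance_ratio[: base.n_components],
            atol=1e-8,
        )

    def test_scores_covariance_diagonal(self):
        rng = np.random.default_rng(2)
        scaled, _, _, _ = scale_center(pd.DataFrame(rng.random((6, 9))))
        res = pca(scaled)
        C = np.cov(res.scores.to_numpy(), rowvar=False)
        off = C - np.diag(np.diag(C))
        assert np.max(np.abs(off)) < 1e-10

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame([[1.0, 2.0]]))


class TestRanking:
    def test_zero_loading_never_outranks_nonzero(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((4, 5)),
                         columns=[f"c_{i * 100 + 50}" for i in range(5)])
        X["c_999"] = [0.3, 0.3, 0.3, 0.31]  # near-constant, tiny loading
        res = pca(scale_center(X)[0])
        ranked = rank_informative(res, components=[1], k=6)[1]
        load = res.loadings["PC1"].abs()
        assert load[ranked[0]] >= load[ranked[-1]]
        for a, b in zip(ranked, ranked[1:]):
            assert load[a] >= load[b] - 1e-12

    def test_k_exceeding_variant_count_returns_all(self, fixture_results):
        ranked = fixture_results.rank_informative(components=[1], k=1000)[1]
        assert len(ranked) == 27

    def test_nonpositive_k_rejected(self, fixture_results):
        with pytest.raises(ValueError):
            fixture_results.rank_informative(k=0)

    def test_planted_axis_variants_occupy_top_ranks(self):
        # the dominant axis is carried by 8 identically-patterned planted
        # variants; 3 columns of unstructured noise load lower on PC1
        rng = np.random.default_rng(4)
        rows = {}
        for i in range(8):
            rows[f"c_{i * 100 + 100}"] = [1.0, 0.0, 0.0, 0.0]  # split axis
        for i in range(3):
            rows[f"c_{i * 100 + 5000}"] = list(rng.random(4))
        X = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["A", "B", "C", "D"]).T
        res = pca(scale_center(X)[0])
        top8 = set(rank_informative(res, components=[1], k=8)[1])
        assert top8 == {f"c_{i * 100 + 100}" for i in range(8)}


class TestDiagnosticRules:
    def test_species_specific_published_rows(self, table4):
        values = fixtures.combined_frequencies().loc[table4.index]
        calls = call_species_specific(values, SP_MAP)
        assert len(calls) == 15
        got = {c.variant_id: c.target for c in calls}
        assert got == dict(table4["specific"])

    def test_single_ambiguous_species_blocks_call(self):
        values = freq_frame({"v1": (0.5, 0.0, 1.0, 1.0, 1.0)})
        assert call_species_specific(values, SP_MAP) == []

    def test_replicate_disagreement_blocks_call(self):
        values = freq_frame({"v1": (1.0, 0.0, 1.0, 1.0, 0.0)})  # TH04 reps differ
        assert call_species_specific(values, SP_MAP) == []

    def test_pairwise_published_rows(self, table5):
        values = fixtures.combined_frequencies().loc[table5.index]
        calls = call_pairwise(values, SP_MAP)
        assert len(calls) == 12
        for c in calls:
            low = tuple(sorted(x.strip() for x in
                               table5.loc[c.variant_id, "low"].split("x")))
            high = tuple(sorted(x.strip() for x in
                                table5.loc[c.variant_id, "high"].split("x")))
            assert (c.low_pair, c.high_pair) == (low, high)

    def test_three_one_split_is_not_pairwise(self):
        values = freq_frame({"v1": (1.0, 1.0, 1.0, 0.0, 0.0)})
        assert call_pairwise(values, SP_MAP) == []
        assert len(call_species_specific(values, SP_MAP)) == 1

    def test_call_sets_disjoint_on_fixture(self, fixture_results):
        spec = {c.variant_id for c in fixture_results.specific_calls}
        pair = {c.variant_id for c in fixture_results.pairwise_calls}
        assert spec.isdisjoint(pair)
        assert len(spec | pair) == 27

    def test_unknown_column_species_rejected(self):
        values = freq_frame({"v1": (1, 0, 1, 1, 1)}).rename(columns={"PA03": "XX"})
        with pytest.raises(ValueError):
            call_species_specific(values, SP_MAP)

    def test_complement_invariance(self, fixture_results):
        values = fixtures.combined_frequencies()
        flipped = 1.0 - values
        spec = call_species_specific(flipped, SP_MAP)
        assert {c.variant_id: c.target for c in spec} == {
            c.variant_id: c.target for c in fixture_results.specific_calls
        }
        pair = {c.variant_id: (c.low_pair, c.high_pair)
                for c in call_pairwise(flipped, SP_MAP)}
        for c in fixture_results.pairwise_calls:
            assert pair[c.variant_id] == (c.high_pair, c.low_pair)  # sides swap

    def test_complement_preserves_pca_variance(self, fixture_results):
        flipped = DiagnosticPanel(fixtures.combined_dosage().complement()).fit()
        assert np.allclose(flipped.pca.variance_ratio,
                           fixture_results.pca.variance_ratio, atol=1e-12)


class TestDistances:
    def test_symmetric_zero_diagonal(self, fixture_results):
        d = fixture_results.distances
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)

    def test_identical_rows_distance_zero(self):
        m = pd.DataFrame([[0.1, 0.9, 0.4], [0.1, 0.9, 0.4]], index=["a", "b"])
        d, order = euclidean_matrix(m)
        assert d.loc["a", "b"] == 0.0
        assert set(order) == {"a", "b"}

    def test_closest_pair_is_td01_th04(self, fixture_results):
        d = fixture_results.distances
        off = d.where(~np.eye(len(d), dtype=bool))
        pair = tuple(sorted(off.stack().idxmin()))
        assert pair == ("TD01", "TH04")

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            euclidean_matrix(pd.DataFrame([[1.0, 2.0]]))


class TestPanelSummary:
    def test_summary_reports_panel_composition(self, fixture_results):
        text = fixture_results.summary()
        assert "species-specific calls:   15" in text
        assert "pairwise calls:           12" in text
        assert "panel size (union):       27" in text
        assert "TD01" in text

    def test_specific_counts_match_study_design(self, fixture_results):
        counts = fixture_results.specific_counts()
        assert counts.to_dict() == {"PA03": 4, "TD01": 4, "TP02": 5, "TH04": 2}

    def test_invalid_thresholds_rejected(self):
        panel = DiagnosticPanel(fixtures.combined_dosage())
        with pytest.raises(ValueError):
            panel.fit(t_low=0.9, t_high=0.1)
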