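import numpy as np
import pytest

from epicompress import SyntheticWorld, WorldConfig
from epicompress.imputation import (
    MarkImputation,
    best_correlated_baseline,
    fit_full_models,
    impute_all_marks_cv,
    mark_type_overrepresentation,
    same_mark_other_cell_baseline,
    select_predictor_columns,
)
from epicompress.matrix import EnrichmentMatrix, MarkMeta
from epicompress.models import fit_ols, pearson_with_pvalue, predict


def matrix_from_values(values, marks, **kw):
    genes = [f"g{i}" for i in range(values.shape[0])]
    return EnrichmentMatrix(values, genes, marks, n_bins=1, **kw)


@pytest.fixture(scope="module")
def meth_matrix():
    rng = np.random.default_rng(0)
    marks = [
        MarkMeta("DNAme", "epigenetic_mark", "absolute"),
        MarkMeta("DNAme", "epigenetic_mark", "cpg_normalized"),
        MarkMeta("H3K4me3"),
        MarkMeta("CTCF", "transcription_factor"),
    ]
    return matrix_from_values(rng.random((50, 4)), marks)


class TestSelectPredictorColumns:
    def test_methylation_target_uses_normalized_drops_absolute(self, meth_matrix):
        X, y, labels = select_predictor_columns(meth_matrix, "DNAme[cpg_normalized]")
        np.testing.assert_array_equal(
            y, meth_matrix.mark_values("DNAme[cpg_normalized]").ravel()
        )
        assert labels == ["H3K4me3", "CTCF"]

    def test_other_target_keeps_absolute_drops_normalized(self, meth_matrix):
        X, y, labels = select_predictor_columns(meth_matrix, "H3K4me3")
        assert labels == ["DNAme[absolute]", "CTCF"]

    def test_no_methylation_all_others(self, small_matrix):
        X, y, labels = select_predictor_columns(small_matrix, "MK01")
        assert len(labels) == small_matrix.n_marks - 1
        assert "MK01" not in labels

    def test_absent_target_errors(self, small_matrix):
        with pytest.raises(KeyError):
            select_predictor_columns(small_matrix, "nope")


class TestImputeAllMarks:
    def test_planted_linear_world_recovers_target_r(self, small_matrix):
        rep = impute_all_marks_cv(small_matrix, seed=0)
        assert rep.median_r == pytest.approx(0.9, abs=0.08)  # small n, wide band
        assert len(rep.per_mark) == small_matrix.n_marks

    def test_pure_noise_world_median_near_zero(self):
        rng = np.random.default_rng(1)
        marks = [MarkMeta(f"m{i}") for i in range(8)]
        m = matrix_from_values(rng.random((1000, 8)), marks)
        rep = impute_all_marks_cv(m, seed=1)
        assert rep.per_mark["r"].abs().median() < 0.08

    def test_constant_column_reported_not_poisoning(self):
        rng = np.random.default_rng(2)
        vals = rng.random((100, 4))
        vals[:, 3] = 0.5
        marks = [MarkMeta(f"m{i}") for i in range(4)]
        m = matrix_from_values(vals, marks)
        with pytest.warns(UserWarning, match="skipped"):
            rep = impute_all_marks_cv(m, seed=2)
        assert "m3" in rep.failures
        assert len(rep.per_mark) == 3


class TestFullModels:
    def test_recovers_planted_pairwise_weight(self):
        rng = np.random.default_rng(3)
        b = rng.standard_normal(2000)
        a = 0.8 * b + 0.1 * rng.standard_normal(2000)
        c = rng.standard_normal(2000)
        marks = [MarkMeta("A"), MarkMeta("B"), MarkMeta("C")]
        m = matrix_from_values(np.column_stack([a, b, c]), marks)
        fits = fit_full_models(m)
        assert fits["A"].weights["B"] == pytest.approx(0.8, abs=0.02)
        assert abs(fits["A"].weights["C"]) < 0.02

    def test_independent_marks_weights_near_zero(self):
        rng = np.random.default_rng(4)
        marks = [MarkMeta(f"m{i}") for i in range(6)]
        m = matrix_from_values(rng.standard_normal((2000, 6)), marks)
        fits = fit_full_models(m)
        w = np.concatenate([f.coef for f in fits.values()])
        assert np.median(np.abs(w)) < 0.05

    def test_in_sample_r_beats_best_single_mark(self, small_matrix):
        """OLS over all marks dominates any single-predictor baseline."""
        for meta in small_matrix.marks:
            X, y, _ = select_predictor_columns(small_matrix, meta)
            fit = fit_ols(X, y)
            r_model, _ = pearson_with_pvalue(y, predict(fit, X))
            _, r_single = best_correlated_baseline(small_matrix, meta)
            assert r_model >= abs(r_single) - 1e-9


class TestOverrepresentation:
    def _weights(self, seed=5):
        rng = np.random.default_rng(seed)
        # epigenetic marks load on one shared factor; TFs independent
        f = rng.standard_normal(1500)
        em = [f * 1.0 + 0.3 * rng.standard_normal(1500) for _ in range(4)]
        tf = [rng.standard_normal(1500) for _ in range(4)]
        marks = [MarkMeta(f"EM{i}", "epigenetic_mark") for i in range(4)]
        marks += [MarkMeta(f"TF{i}", "transcription_factor") for i in range(4)]
        m = matrix_from_values(np.column_stack(em + tf), marks)
        return fit_full_models(m), marks

    def test_coupled_type_is_overrepresented(self):
        fits, marks = self._weights()
        df = mark_type_overrepresentation(fits, marks, q=0.9)
        row = df[(df.target_type == "epigenetic_mark")
                 & (df.input_type == "epigenetic_mark")].iloc[0]
        assert row.frequency > row.baseline

    def test_frequencies_sum_to_one_per_target_type(self):
        fits, marks = self._weights()
        df = mark_type_overrepresentation(fits, marks, q=0.9)
        sums = df.dropna().groupby("target_type")["frequency"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0)

    def test_quantile_cutoff_count(self):
        fits, marks = self._weights()
        df = mark_type_overrepresentation(fits, marks, q=0.95)
        n_pooled = sum(len(f.coef) for f in fits.values())
        assert df["n_top_weights"].groupby(df["target_type"]).first().sum() == \
            pytest.approx(n_pooled * 0.05, abs=2)

    def test_single_type_world_trivial(self):
        rng = np.random.default_rng(6)
        marks = [MarkMeta(f"m{i}", "coregulator") for i in range(3)]
        m = matrix_from_values(rng.random((50, 3)), marks)
        df = mark_type_overrepresentation(fit_full_models(m), marks)
        assert (df["frequency"] == 1.0).all()


class TestNormalizationRobustness:
    def test_medians_insensitive_to_quantile_cutoff(self, small_world):
        """Imputation medians under q=0.01 and q=0.05 scaling agree closely."""
        m1 = small_world.enrichment_matrix("cellA", q=0.01)
        m5 = small_world.enrichment_matrix("cellA", q=0.05)
        r1 = impute_all_marks_cv(m1, seed=0).median_r
        r5 = impute_all_marks_cv(m5, seed=0).median_r
        assert abs(r1 - r5) < 0.05


class TestBicComparison:
    def test_all_mark_model_has_smaller_bic_than_restricted_panel(self):
        """When the extra marks carry signal, the all-mark model wins on BIC."""
        from epicompress.imputation import _panel_design
        from epicompress.models import bic_linear

        w = SyntheticWorld(WorldConfig.imputation_world(
            n_genes=1500, n_marks=12, seed=9))
        m = w.enrichment_matrix("cellA")
        target = m.marks[-1]
        X_all, y, _ = select_predictor_columns(m, target)
        X_sub, _ = _panel_design(m, m.marks[:6], target)
        assert bic_linear(fit_ols(X_all, y)) < bic_linear(fit_ols(X_sub, y))


class TestBaselines:
    def test_identical_mark_gives_r_one(self):
        rng = np.random.default_rng(7)
        a = rng.random(100)
        marks = [MarkMeta("A"), MarkMeta("B"), MarkMeta("C")]
        m = matrix_from_values(np.column_stack([a, a, rng.random(100)]), marks)
        best, r = best_correlated_baseline(m, "A")
        assert best == "B" and r == pytest.approx(1.0)

    def test_signed_maximum_rule(self):
        """An anti-correlated predictor is not the 'best correlated' mark."""
        rng = np.random.default_rng(8)
        a = rng.random(200)
        anti = 1 - a + 0.01 * rng.standard_normal(200)
        weak = 0.3 * a + rng.random(200)
        marks = [MarkMeta("A"), MarkMeta("ANTI"), MarkMeta("WEAK")]
        m = matrix_from_values(np.column_stack([a, anti, weak]), marks)
        best, r = best_correlated_baseline(m, "A")
        assert best == "WEAK" and 0 < r < 1

    def test_same_mark_other_cell(self, small_world):
        m = small_world.enrichment_matrix("cellA")
        assert same_mark_other_cell_baseline(m, m, "MK01") == pytest.approx(1.0)
        other = m.subset_genes(m.genes[:10])
        renamed = EnrichmentMatrix(
            other.values, [f"x{i}" for i in range(10)], other.marks
        )
        with pytest.raises(ValueError, match="shared"):
            same_mark_other_cell_baseline(m, renamed, "MK01")


class TestModelObjectSurface:
    def test_fit_returns_results_with_summary(self, small_matrix):
        res = MarkImputation(small_matrix).fit(seed=0)
        text = res.summary()
        assert "median Pearson r" in text
        assert res.median_r == pytest.approx(
            impute_all_marks_cv(small_matrix, seed=0).median_r
        )
        wt = res.weight_table()
        assert wt.shape[0] == small_matrix.n_marks
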