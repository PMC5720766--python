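import numpy as np
import pytest

from epicompress import SyntheticWorld, WorldConfig
from epicompress.imputation import _panel_design, impute_all_marks_cv
from epicompress.matrix import EnrichmentMatrix, MarkMeta
from epicompress.models import kfold_cv, make_folds
from epicompress.selection import (
    IHEC_PANEL,
    greedy_select,
    single_mark_ranking,
    subset_impute_cv,
    subset_transfer,
    threshold_curve,
)


@pytest.fixture(scope="module")
def hub_world():
    return SyntheticWorld(WorldConfig.hub_world(seed=31))


@pytest.fixture(scope="module")
def hub_matrix(hub_world):
    return hub_world.enrichment_matrix("cellA")


def exhaustive_two_rounds(matrix, k=10, seed=0):
    """Independent oracle: best ordered pair maximising round-wise median r."""
    folds = make_folds(matrix.n_genes, k, seed)
    names = [m.column_name for m in matrix.marks]
    idx = list(range(len(names)))

    def median_r(panel, targets):
        rs = []
        for t in targets:
            X, y = _panel_design(
                matrix, [matrix.marks[i] for i in panel], matrix.marks[t]
            )
            rs.append(kfold_cv(X, y, k=k, folds=folds).pearson_r)
        return float(np.median(rs))

    v1 = [median_r([j], [t for t in idx if t != j]) for j in idx]
    first = int(np.argmax(v1))
    rest = [t for t in idx if t != first]
    v2 = [median_r([first, j], [t for t in rest if t != j]) for j in rest]
    second = rest[int(np.argmax(v2))]
    return names[first], names[second]


class TestSubsetImpute:
    def test_all_but_one_equals_full_imputation(self, small_matrix):
        target = small_matrix.marks[-1].column_name
        panel = [m.column_name for m in small_matrix.marks[:-1]]
        rep = subset_impute_cv(small_matrix, panel, seed=3)
        full = impute_all_marks_cv(small_matrix, seed=3)
        assert list(rep.per_mark.index) == [target]
        assert rep.per_mark.loc[target, "r"] == pytest.approx(
            full.per_mark.loc[target, "r"], abs=1e-12
        )

    def test_spanning_panel_recaptures_most_information(self, small_matrix):
        """A panel spanning the latent space predicts nearly as well as all marks."""
        panel = [m.column_name for m in small_matrix.marks[:4]]
        rep = subset_impute_cv(small_matrix, panel, seed=3)
        full = impute_all_marks_cv(small_matrix, seed=3)
        assert rep.median_r > full.median_r - 0.1

    def test_orthogonal_signal_not_recaptured(self):
        rng = np.random.default_rng(5)
        z1 = rng.standard_normal(600)
        z2 = rng.standard_normal(600)
        cols = [z1 + 0.2 * rng.standard_normal(600) for _ in range(3)]
        cols += [z2 + 0.2 * rng.standard_normal(600) for _ in range(3)]
        marks = [MarkMeta(f"p{i}") for i in range(3)] + [
            MarkMeta(f"o{i}") for i in range(3)
        ]
        genes = [f"g{i}" for i in range(600)]
        m = EnrichmentMatrix(np.column_stack(cols), genes, marks)
        rep = subset_impute_cv(m, ["p0", "p1", "p2"], seed=5)
        assert rep.per_mark["r"].abs().max() < 0.15

    def test_missing_panel_mark_errors(self, small_matrix):
        with pytest.raises(KeyError, match="absent"):
            subset_impute_cv(small_matrix, IHEC_PANEL)


class TestSubsetTransfer:
    def test_same_matrix_both_sides(self, small_matrix):
        panel = [m.column_name for m in small_matrix.marks[:3]]
        res = subset_transfer(small_matrix, small_matrix, panel)
        assert len(res) == small_matrix.n_marks - 3
        assert all(t.r > 0.4 for t in res)  # in-sample, spanning panel

    def test_shared_rules_transfer_with_restricted_panel(self):
        w = SyntheticWorld(WorldConfig.imputation_world(
            n_genes=500, n_marks=8, n_cell_lines=2, seed=33))
        a = w.enrichment_matrix("cellA")
        b = w.enrichment_matrix("cellB")
        panel = ["MK01", "MK02", "MK03"]
        res = subset_transfer(a, b, panel)
        intra = subset_impute_cv(a, panel, seed=33)
        med_t = np.median([t.r for t in res])
        assert med_t == pytest.approx(intra.median_r, abs=0.07)


class TestRankingAndGreedy:
    def test_hub_ranked_first(self, hub_world, hub_matrix):
        rank = single_mark_ranking(hub_matrix, seed=31)
        assert rank.iloc[0]["mark"] == hub_world.truth.expected_first_selection

    def test_null_world_medians_near_zero(self):
        rng = np.random.default_rng(6)
        marks = [MarkMeta(f"m{i}") for i in range(5)]
        genes = [f"g{i}" for i in range(800)]
        m = EnrichmentMatrix(rng.random((800, 5)), genes, marks)
        rank = single_mark_ranking(m, seed=6)
        # CV on pure noise has a small negative bias; no mark looks informative
        assert rank["median_r"].max() < 0.05
        assert rank["median_r"].abs().max() < 0.15

    def test_round_one_equals_ranking(self, hub_matrix):
        rank = single_mark_ranking(hub_matrix, seed=7)
        trace = greedy_select(hub_matrix, n_rounds=1, seed=7)
        scores = trace.round_scores[0]
        assert scores.sort_values(ascending=False).index[0] == rank.iloc[0]["mark"]
        np.testing.assert_allclose(
            np.sort(scores.to_numpy()),
            np.sort(rank["median_r"].to_numpy()),
        )

    def test_greedy_matches_exhaustive_two_rounds(self):
        """Greedy equals brute-force ordered-pair search on small worlds."""
        worlds = [
            WorldConfig.hub_world(n_marks=5, n_genes=300, seed=s)
            for s in (1, 2)
        ] + [
            WorldConfig.imputation_world(n_genes=300, n_marks=6, seed=s)
            for s in (3, 4)
        ]
        for cfg in worlds:
            m = SyntheticWorld(cfg).enrichment_matrix("cellA")
            trace = greedy_select(m, n_rounds=2, k=10, seed=9)
            oracle = exhaustive_two_rounds(m, k=10, seed=9)
            assert tuple(trace.selected) == oracle

    def test_redundant_twin_selected_late(self):
        """Of two perfectly correlated informative marks only one is selected
        early; the twin adds nothing."""
        rng = np.random.default_rng(8)
        z = rng.standard_normal(600)
        info = z + 0.3 * rng.standard_normal(600)
        twin = info.copy()
        others = [0.8 * z + 0.7 * rng.standard_normal(600) for _ in range(4)]
        marks = [MarkMeta("INFO"), MarkMeta("TWIN")] + [
            MarkMeta(f"m{i}") for i in range(4)
        ]
        genes = [f"g{i}" for i in range(600)]
        m = EnrichmentMatrix(
            np.column_stack([info, twin] + others), genes, marks
        )
        trace = greedy_select(m, seed=8)
        first_twin = {"INFO", "TWIN"} & set(trace.selected[:1])
        assert len(first_twin) == 1
        other_twin = ({"INFO", "TWIN"} - first_twin).pop()
        assert trace.selected.index(other_twin) >= 4

    def test_full_run_is_permutation(self, small_matrix):
        trace = greedy_select(small_matrix, seed=10)
        assert sorted(trace.ordervec) == list(range(small_matrix.n_marks))

    def test_selected_median_r_rises_then_plateaus(self, hub_matrix):
        trace = greedy_select(hub_matrix, seed=11)
        scores = [s for s in trace.selected_median_r if not np.isnan(s)]
        assert all(b >= a - 0.02 for a, b in zip(scores, scores[1:]))


class TestThresholdCurve:
    def test_monotone_and_sentinel(self, hub_matrix):
        df = threshold_curve(hub_matrix, [0.05, 0.5, 0.8, 0.99], seed=12)
        reached = df[df.n_marks > 0]
        assert (reached.n_marks.diff().dropna() >= 0).all()
        assert df.iloc[0]["n_marks"] == 1  # any informative mark clears 0.05
        assert df.iloc[-1]["n_marks"] == -1  # above the noise ceiling

    def test_threshold_bounds(self, hub_matrix):
        with pytest.raises(ValueError):
            threshold_curve(hub_matrix, [1.5], seed=0)
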