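"""Ranking and greedy selection of marks by information content.

The information content of a mark set is the median 10-fold-CV Pearson r
with which linear models on that set predict all remaining marks.  The
greedy algorithm starts from the empty set and, each round, adds the
candidate mark whose inclusion maximises that median over the
not-yet-selected targets; the resulting order traces how quickly a small
panel saturates the predictable signal.  The six-mark IHEC reference panel
(H3K4me1, H3K4me3, H3K9me3, H3K27ac, H3K27me3, H3K36me3) is provided as a
fixed predictor set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputation import ImputationReport, impute_all_marks_cv, _panel_design, _target_marks
from .matrix import EnrichmentMatrix
from .models import kfold_cv, make_folds
from .transfer import TransferResult, _aligned_pair, transfer_predict

__all__ = [
    "IHEC_PANEL",
    "SelectionTrace",
    "subset_impute_cv",
    "subset_transfer",
    "single_mark_ranking",
    "greedy_select",
    "threshold_curve",
]

IHEC_PANEL = (
    "H3K4me1", "H3K4me3", "H3K9me3", "H3K27ac", "H3K27me3", "H3K36me3",
)


@dataclass
class SelectionTrace:
    selected: list[str]  # mark column names, in selection order
    ordervec: list[int]  # selected mark indices (into the candidate list)
    candidates: list[str]
    round_scores: list[pd.Series]  # per round: candidate -> median r
    selected_median_r: list[float]  # score of the winner each round
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "round": np.arange(1, len(self.selected) + 1),
            "mark": self.selected,
            "median_r": self.selected_median_r,
        })


def subset_impute_cv(
    matrix: EnrichmentMatrix,
    predictors=IHEC_PANEL,
    k: int = 10,
    seed: int | None = 0,
) -> ImputationReport:
    """Predict every non-panel mark from a fixed predictor panel (10-fold CV)."""
    predictors = list(predictors)
    missing = [p for p in predictors if _missing(matrix, p)]
    if missing:
        raise KeyError(f"panel marks absent from matrix: {missing}")
    n_targets = sum(
        1 for t in _target_marks(matrix)
        if not any(matrix.mark_index(p) == matrix.mark_index(t) for p in predictors)
    )
    if n_targets == 0:
        raise ValueError("no non-panel target marks")
    return impute_all_marks_cv(matrix, k=k, seed=seed, predictors=predictors)


def _missing(matrix: EnrichmentMatrix, mark) -> bool:
    try:
        matrix.mark_index(mark)
        return False
    except KeyError:
        return True


def subset_transfer(
    matrix_a: EnrichmentMatrix,
    matrix_b: EnrichmentMatrix,
    predictors=IHEC_PANEL,
) -> list[TransferResult]:
    """Cross-cell-line prediction of common non-panel marks from the panel."""
    a, b = _aligned_pair(matrix_a, matrix_b)
    predictors = list(predictors)
    panel_idx = {a.mark_index(p) for p in predictors}
    out = []
    for t in _target_marks(a):
        if a.mark_index(t) in panel_idx:
            continue
        keep = predictors + [t]
        out.append(
            transfer_predict(a.subset_marks(keep), b.subset_marks(keep), t,
                             align=False)
        )
    return out


def _panel_median_r(
    matrix: EnrichmentMatrix,
    panel_idx: list[int],
    target_idx: list[int],
    k: int,
    folds: np.ndarray,
) -> float:
    rs = []
    for ti in target_idx:
        X, y = _panel_design(
            matrix, [matrix.marks[i] for i in panel_idx], matrix.marks[ti]
        )
        res = kfold_cv(X, y, k=k, model="ols", folds=folds)
        rs.append(res.pearson_r)
    return float(np.median(rs))


def single_mark_ranking(
    matrix: EnrichmentMatrix, k: int = 10, seed: int | None = 0
) -> pd.DataFrame:
    """Each mark's median CV r over all other targets when used alone.

    Identical to round 1 of :func:`greedy_select` (same folds); ties sort
    by mark name.
    """
    trace = greedy_select(matrix, n_rounds=1, k=k, seed=seed)
    scores = trace.round_scores[0]
    df = pd.DataFrame({"mark": scores.index, "median_r": scores.to_numpy()})
    return df.sort_values(["median_r", "mark"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)


def greedy_select(
    matrix: EnrichmentMatrix,
    n_rounds: int | None = None,
    k: int = 10,
    seed: int | None = 0,
) -> SelectionTrace:
    """Greedy forward selection of marks by information content.

    Each round, every unselected candidate j is scored by the median
    10-fold-CV Pearson r of linear models predicting every remaining target
    (candidates ∪ selected as inputs; the candidate's own predictability is
    not part of its score); the argmax joins the selected set.  Ties break
    to the lowest candidate index.  Folds are drawn once per run and shared
    within and across rounds.  DNA methylation candidates enter as the
    absolute column and are predicted via the normalised column, as in the
    all-marks models.
    """
    cand_idx = [
        i for i, m in enumerate(matrix.marks)
        if m.methylation_flavor != "cpg_normalized"
    ]
    candidates = [matrix.marks[i].column_name for i in cand_idx]
    n = len(cand_idx)
    if n_rounds is None:
        n_rounds = n
    if n_rounds > n:
        raise ValueError(f"n_rounds={n_rounds} exceeds {n} candidate marks")
    folds = make_folds(matrix.n_genes, k, seed)
    # targets are scored through _target_marks semantics: methylation target
    # is its normalized flavor
    target_of = {}
    for i in cand_idx:
        m = matrix.marks[i]
        ti = i
        if m.methylation_flavor == "absolute":
            ti = next(
                j for j, mm in enumerate(matrix.marks)
                if mm.mark_name == m.mark_name
                and mm.methylation_flavor == "cpg_normalized"
            )
        target_of[i] = ti

    selected: list[int] = []  # positions into cand_idx
    trace = SelectionTrace(selected=[], ordervec=[], candidates=candidates,
                           round_scores=[], selected_median_r=[], seed=seed)
    for _ in range(n_rounds):
        remaining = [j for j in range(n) if j not in selected]
        scores = {}
        for j in remaining:
            panel = [cand_idx[s] for s in selected] + [cand_idx[j]]
            targets = [target_of[cand_idx[t]] for t in remaining if t != j]
            if not targets:
                # final round: no unselected targets remain, score undefined
                scores[candidates[j]] = np.nan
                continue
            scores[candidates[j]] = _panel_median_r(
                matrix, panel, targets, k, folds
            )
        v = pd.Series(scores)
        order = [candidates[j] for j in remaining]
        v = v.loc[order]
        best_pos = int(np.argmax(v.to_numpy()))  # first max: lowest index
        winner = remaining[best_pos]
        selected.append(winner)
        trace.selected.append(candidates[winner])
        trace.ordervec.append(winner)
        trace.round_scores.append(v)
        trace.selected_median_r.append(float(v.iloc[best_pos]))
    return trace


def threshold_curve(
    matrix: EnrichmentMatrix,
    thresholds,
    k: int = 10,
    seed: int | None = 0,
    trace: SelectionTrace | None = None,
    unreachable: int = -1,
) -> pd.DataFrame:
    """Minimal number of greedily-selected marks exceeding each median-r threshold.

    Runs greedy selection once; for each threshold, reports the first round
    whose winning median r exceeds it (``unreachable`` sentinel otherwise).
    """
    if trace is None:
        trace = greedy_select(matrix, k=k, seed=seed)
    scores = trace.selected_median_r
    rows = []
    for t in thresholds:
        if not 0 < t < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        n_marks = unreachable
        for i, s in enumerate(scores, start=1):
            if s > t:
                n_marks = i
                break
        rows.append({"threshold": t, "n_marks": n_marks})
    return pd.DataFrame(rows)
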