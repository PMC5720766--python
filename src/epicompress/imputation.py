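"""Predicting each mark from all other marks within one constellation.

Every mark in an enrichment matrix is regressed on all the others with an
ordinary linear model under 10-fold CV; the per-mark Pearson r between
measured and out-of-fold predicted enrichments (and the median over marks)
quantify how redundant the mark panel is.  DNA methylation follows special
column rules: when methylation is the target, the CpG-normalised column is
predicted and the absolute column is excluded from the predictors; for any
other target the CpG-normalised column is dropped and the absolute one kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import EnrichmentMatrix, MarkMeta, REGULATORY_TYPES
from .models import (
    ConstantInputError,
    CVResult,
    LinearFit,
    fit_ols,
    kfold_cv,
    make_folds,
    pearson_with_pvalue,
)

__all__ = [
    "ImputationReport",
    "select_predictor_columns",
    "impute_all_marks_cv",
    "fit_full_models",
    "mark_type_overrepresentation",
    "best_correlated_baseline",
    "same_mark_other_cell_baseline",
    "MarkImputation",
    "ImputationResults",
]


@dataclass
class ImputationReport:
    constellation: tuple[str, str, str]
    per_mark: pd.DataFrame  # index: target column name; columns r, p, n
    cv_results: dict[str, CVResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def median_r(self) -> float:
        return float(self.per_mark["r"].median())


def _target_marks(matrix: EnrichmentMatrix) -> list[MarkMeta]:
    """Eligible prediction targets: every mark once, methylation via its
    CpG-normalised column only."""
    return [m for m in matrix.marks if m.methylation_flavor != "absolute"]


def select_predictor_columns(
    matrix: EnrichmentMatrix, target
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a matrix into (X, y, predictor column labels) for one target.

    Methylation rules: predicting methylation uses the cpg_normalized column
    as y and drops the absolute column from X; predicting anything else
    drops the cpg_normalized column from X (total methylation presence is
    kept as a predictor).
    """
    ti = matrix.mark_index(target)
    tmeta = matrix.marks[ti]
    if tmeta.methylation_flavor == "absolute":
        # the methylation target is its normalized flavor
        ti = next(
            i for i, m in enumerate(matrix.marks)
            if m.mark_name == tmeta.mark_name
            and m.methylation_flavor == "cpg_normalized"
        )
        tmeta = matrix.marks[ti]
    drop_flavor = "absolute" if tmeta.methylation_flavor == "cpg_normalized" else "cpg_normalized"
    keep = [
        i for i, m in enumerate(matrix.marks)
        if i != ti and m.methylation_flavor != drop_flavor
    ]
    B = matrix.n_bins
    cols = np.concatenate([np.arange(i * B, (i + 1) * B) for i in keep])
    y = matrix.values[:, ti * B:(ti + 1) * B]
    if B == 1:
        y = y.ravel()
    labels = []
    for i in keep:
        m = matrix.marks[i]
        if B == 1:
            labels.append(m.column_name)
        else:
            labels.extend(f"{m.column_name}:bin{b + 1}" for b in range(B))
    return matrix.values[:, cols], y, labels


def impute_all_marks_cv(
    matrix: EnrichmentMatrix,
    k: int = 10,
    seed: int | None = 0,
    predictors: list | None = None,
) -> ImputationReport:
    """10-fold-CV prediction of every eligible target mark from the others.

    Folds are shared across targets for comparability.  ``predictors``
    optionally restricts the input marks to a fixed panel (targets are then
    all non-panel marks); see :func:`epicompress.selection.subset_impute_cv`.
    """
    if matrix.n_marks < 3:
        raise ValueError("need at least 3 marks")
    folds = make_folds(matrix.n_genes, k, seed)
    rows = {}
    cv_results = {}
    failures = {}
    for tmeta in _target_marks(matrix):
        if predictors is not None and any(
            matrix.mark_index(p) == matrix.mark_index(tmeta) for p in predictors
        ):
            continue
        try:
            if predictors is None:
                X, y, _ = select_predictor_columns(matrix, tmeta)
            else:
                X, y = _panel_design(matrix, predictors, tmeta)
            res = kfold_cv(X, y, k=k, model="ols", seed=seed, folds=folds,
                           target=tmeta.column_name)
        except ConstantInputError as exc:
            failures[tmeta.column_name] = str(exc)
            warnings.warn(
                f"target {tmeta.column_name} skipped: {exc}"
            )
            continue
        rows[tmeta.column_name] = {
            "r": res.pearson_r, "p": res.p_value, "n": matrix.n_genes,
        }
        cv_results[tmeta.column_name] = res
    per_mark = pd.DataFrame.from_dict(rows, orient="index")
    return ImputationReport(
        constellation=matrix.constellation, per_mark=per_mark,
        cv_results=cv_results, failures=failures,
    )


def _panel_design(matrix: EnrichmentMatrix, predictors: list, target: MarkMeta):
    """Design for a fixed predictor panel (methylation flavors as usual)."""
    drop_flavor = (
        "absolute" if target.methylation_flavor == "cpg_normalized"
        else "cpg_normalized"
    )
    idx = []
    for p in predictors:
        i = matrix.mark_index(p)
        if matrix.marks[i].methylation_flavor == drop_flavor:
            continue
        idx.append(i)
    B = matrix.n_bins
    cols = np.concatenate([np.arange(i * B, (i + 1) * B) for i in idx])
    ti = matrix.mark_index(target)
    y = matrix.values[:, ti * B:(ti + 1) * B]
    return matrix.values[:, cols], (y.ravel() if B == 1 else y)


def fit_full_models(matrix: EnrichmentMatrix) -> dict[str, LinearFit]:
    """One 100%-of-genes linear model per eligible target mark."""
    table = {}
    for tmeta in _target_marks(matrix):
        X, y, labels = select_predictor_columns(matrix, tmeta)
        table[tmeta.column_name] = fit_ols(X, y, columns=labels)
    return table


def mark_type_overrepresentation(
    weights: dict[str, LinearFit],
    meta: list[MarkMeta],
    q: float = 0.95,
) -> pd.DataFrame:
    """Input-mark-type frequencies among the largest model weights.

    Absolute weights of all models are pooled, restricted to the four
    regulatory mark types on both the target and the input side; weights
    above the pooled q-quantile are tallied by (target type, input type) and
    reported as relative frequencies next to each input type's baseline
    frequency among predictor columns.
    """
    type_of = {}
    for m in meta:
        type_of[m.column_name] = m.mark_type
        type_of.setdefault(m.mark_name, m.mark_type)
    present_types = {
        t for t in (type_of.get(t) for t in weights) if t in REGULATORY_TYPES
    }
    if len({m.mark_type for m in meta if m.mark_type in REGULATORY_TYPES}) < 2:
        if len(present_types) <= 1 and present_types:
            # single-type world: trivially all frequency on that type
            t = next(iter(present_types))
            return pd.DataFrame(
                [{"target_type": t, "input_type": t, "frequency": 1.0,
                  "baseline": 1.0, "n_top_weights": sum(
                      len(f.coef) for f in weights.values())}]
            )
        raise ValueError("need at least 2 regulatory mark types")

    pooled = []  # (|w|, target_type, input_type)
    baseline_counts: dict[str, int] = {}
    for target, fit in weights.items():
        ttype = type_of.get(target.split("[")[0], type_of.get(target))
        if ttype not in REGULATORY_TYPES:
            continue
        cols = fit.columns or []
        for w, col in zip(fit.coef, cols):
            itype = type_of.get(col.split("[")[0], type_of.get(col))
            if itype not in REGULATORY_TYPES:
                continue
            pooled.append((abs(float(w)), ttype, itype))
            baseline_counts[itype] = baseline_counts.get(itype, 0) + 1
    if not pooled:
        raise ValueError("no regulatory-type weights to pool")
    absw = np.array([w for w, _, _ in pooled])
    cutoff = float(np.quantile(absw, q))
    total_baseline = sum(baseline_counts.values())
    rows = []
    target_types = sorted({t for _, t, _ in pooled})
    input_types = sorted(baseline_counts)
    for tt in target_types:
        top = [(w, it) for w, t, it in pooled if t == tt and w > cutoff]
        denom = len(top)
        for it in input_types:
            freq = (
                sum(1 for _, x in top if x == it) / denom if denom else np.nan
            )
            rows.append({
                "target_type": tt, "input_type": it, "frequency": freq,
                "baseline": baseline_counts[it] / total_baseline,
                "n_top_weights": denom,
            })
        if denom == 0:
            warnings.warn(f"no above-cutoff weights for target type {tt}")
    return pd.DataFrame(rows)


def best_correlated_baseline(
    matrix: EnrichmentMatrix, target
) -> tuple[str, float]:
    """The single mark whose enrichment best correlates with the target.

    The maximum *signed* r is used (the model, not the baseline, captures
    anti-correlated predictors).
    """
    if matrix.n_marks < 2:
        raise ValueError("need at least 2 marks")
    X, y, labels = select_predictor_columns(matrix, target)
    best_name, best_r = None, -np.inf
    for j, name in enumerate(labels):
        try:
            r, _ = pearson_with_pvalue(X[:, j], y)
        except ConstantInputError:
            continue
        if r > best_r:
            best_name, best_r = name, r
    return best_name, float(best_r)


def same_mark_other_cell_baseline(
    matrix_a: EnrichmentMatrix, matrix_b: EnrichmentMatrix, mark
) -> float:
    """Pearson r of a mark's enrichment between two cell lines (shared genes)."""
    shared = [g for g in matrix_a.genes if g in set(matrix_b.genes)]
    if not shared:
        raise ValueError("no shared genes between the matrices")
    a = matrix_a.subset_genes(shared).mark_values(mark).ravel()
    b = matrix_b.subset_genes(shared).mark_values(mark).ravel()
    r, _ = pearson_with_pvalue(a, b)
    return r


# ---------------------------------------------------------------------------
# model-object surface


class MarkImputation:
    """Mark-redundancy model for one enrichment matrix.

    ``MarkImputation(matrix).fit()`` runs the all-marks CV imputation and
    the 100%-data weight extraction and returns :class:`ImputationResults`.
    """

    def __init__(self, matrix: EnrichmentMatrix):
        self.matrix = matrix

    def fit(self, k: int = 10, seed: int | None = 0) -> "ImputationResults":
        report = impute_all_marks_cv(self.matrix, k=k, seed=seed)
        full = fit_full_models(self.matrix)
        return ImputationResults(self, report, full, k=k, seed=seed)


class ImputationResults:
    def __init__(self, model: MarkImputation, report: ImputationReport,
                 full_models: dict[str, LinearFit], k: int, seed):
        self.model = model
        self.report = report
        self.full_models = full_models
        self.k = k
        self.seed = seed

    @property
    def median_r(self) -> float:
        return self.report.median_r

    @property
    def per_mark(self) -> pd.DataFrame:
        return self.report.per_mark

    def weight_table(self) -> pd.DataFrame:
        """targets × predictor-columns table of full-data model weights."""
        rows = {}
        for target, fit in self.full_models.items():
            row = dict(fit.weights)
            row["(intercept)"] = fit.intercept
            rows[target] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary(self) -> str:
        cl, gt, rt = self.report.constellation
        lines = [
            "Mark imputation (each mark ~ all other marks, OLS, "
            f"{self.k}-fold CV, seed={self.seed})",
            f"constellation: cell_line={cl or '-'} gene_type={gt} region={rt}",
            f"genes: {self.model.matrix.n_genes}   "
            f"marks: {self.model.matrix.n_marks}",
            f"median Pearson r: {self.median_r:.4f}",
            "",
            self.per_mark.sort_values("r", ascending=False).to_string(
                float_format=lambda v: f"{v:.4g}"
            ),
        ]
        if self.report.failures:
            lines.append(f"skipped targets: {sorted(self.report.failures)}")
        return "\n".join(lines)
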