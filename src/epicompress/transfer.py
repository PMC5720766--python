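"""Cross-cell-line model transfer.

A mark's model is fitted in one cell line on all genes and evaluated on
another cell line's measured enrichments.  Marks whose transferred median
Pearson r falls at least 0.3 below their within-cell-line CV median are
flagged as carrying cell-line-specific rules; cell lines are clustered by
how well one predicts another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .imputation import (
    ImputationReport,
    impute_all_marks_cv,
    select_predictor_columns,
    _target_marks,
)
from .matrix import EnrichmentMatrix
from .models import fit_ols, pearson_with_pvalue, predict

__all__ = [
    "TransferResult",
    "DropReport",
    "shared_mark_projection",
    "transfer_predict",
    "transfer_all_marks",
    "drop_analysis",
    "predictive_similarity_matrix",
    "cluster_cell_lines",
]


@dataclass
class TransferResult:
    source_cell: str
    target_cell: str
    locus_constellation: tuple[str, str]  # (gene_type, region_type)
    mark: str
    r: float
    p: float


@dataclass
class DropReport:
    table: pd.DataFrame  # per mark: intra_r, transfer_r, drop, flagged
    threshold: float

    @property
    def flagged(self) -> list[str]:
        return sorted(self.table.index[self.table["flagged"]])

    def ks_compare(self, group_a: list[str], group_b: list[str]):
        """Two-sample KS test on the drop distributions of two mark groups."""
        da = self.table.loc[[m for m in group_a if m in self.table.index], "drop"]
        db = self.table.loc[[m for m in group_b if m in self.table.index], "drop"]
        return stats.ks_2samp(da.to_numpy(), db.to_numpy())


def shared_mark_projection(
    matrix_a: EnrichmentMatrix, matrix_b: EnrichmentMatrix
) -> tuple[EnrichmentMatrix, EnrichmentMatrix]:
    """Restrict both matrices to their common marks, identically ordered.

    Methylation flavors are matched pairwise: a flavor present in only one
    cell line is dropped from both.
    """
    cols_b = {m.column_name for m in matrix_b.marks}
    common = [m for m in matrix_a.marks if m.column_name in cols_b]
    if len({m.mark_name for m in common}) < 2:
        raise ValueError("fewer than 2 common marks")
    return matrix_a.subset_marks(common), matrix_b.subset_marks(common)


def _aligned_pair(matrix_a, matrix_b):
    a, b = shared_mark_projection(matrix_a, matrix_b)
    shared_genes_b = set(b.genes)
    genes = [g for g in a.genes if g in shared_genes_b]
    if not genes:
        raise ValueError("no shared genes between cell lines")
    return a.subset_genes(genes), b.subset_genes(genes)


def transfer_predict(
    matrix_a: EnrichmentMatrix, matrix_b: EnrichmentMatrix, target,
    align: bool = True,
) -> TransferResult:
    """Fit ``target``'s model on 100% of cell line A, evaluate on cell line B."""
    a, b = _aligned_pair(matrix_a, matrix_b) if align else (matrix_a, matrix_b)
    Xa, ya, labels = select_predictor_columns(a, target)
    fit = fit_ols(Xa, ya, columns=labels)
    Xb, yb, _ = select_predictor_columns(b, target)
    r, p = pearson_with_pvalue(yb, predict(fit, Xb))
    meta = a.marks[a.mark_index(target)]
    return TransferResult(
        source_cell=a.cell_line, target_cell=b.cell_line,
        locus_constellation=(b.gene_type, b.region_type),
        mark=meta.column_name, r=r, p=p,
    )


def transfer_all_marks(
    matrix_a: EnrichmentMatrix, matrix_b: EnrichmentMatrix
) -> list[TransferResult]:
    """transfer_predict for every eligible common target mark."""
    a, b = _aligned_pair(matrix_a, matrix_b)
    return [
        transfer_predict(a, b, m, align=False) for m in _target_marks(a)
    ]


def drop_analysis(
    intra: list[ImputationReport],
    transfers: list[TransferResult],
    threshold: float = 0.3,
) -> DropReport:
    """Per-mark transfer drop: median intra-CV r minus median transfer r.

    Medians pool all available values per mark (cell lines × locus
    constellations for intra; ordered cell-line pairs × locus
    constellations for transfer).  Marks seen in fewer than two cell lines
    are excluded; drops >= threshold are flagged.
    """
    intra_vals: dict[str, list[float]] = {}
    intra_cells: dict[str, set[str]] = {}
    for rep in intra:
        cell = rep.constellation[0]
        for mark, row in rep.per_mark.iterrows():
            intra_vals.setdefault(mark, []).append(float(row["r"]))
            intra_cells.setdefault(mark, set()).add(cell)
    trans_vals: dict[str, list[float]] = {}
    for t in transfers:
        trans_vals.setdefault(t.mark, []).append(t.r)
    rows = {}
    for mark in sorted(set(intra_vals) & set(trans_vals)):
        if len(intra_cells.get(mark, set())) < 2:
            continue
        mi = float(np.median(intra_vals[mark]))
        mt = float(np.median(trans_vals[mark]))
        drop = mi - mt
        rows[mark] = {
            "intra_r": mi, "transfer_r": mt, "drop": drop,
            "flagged": drop >= threshold,
        }
    return DropReport(
        table=pd.DataFrame.from_dict(rows, orient="index"), threshold=threshold
    )


def predictive_similarity_matrix(
    matrices: dict[str, EnrichmentMatrix],
    k: int = 10,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Cell-line × cell-line matrix of median prediction r.

    Rows are target cell lines, columns are source (model-fitting) cell
    lines; the diagonal holds the median within-cell 10-fold-CV r, the
    off-diagonal the median cross-cell transfer r over common marks.
    """
    cells = list(matrices)
    if len(cells) < 2:
        raise ValueError("need at least 2 cell lines")
    out = pd.DataFrame(np.nan, index=cells, columns=cells)
    for src in cells:
        rep = impute_all_marks_cv(matrices[src], k=k, seed=seed)
        out.loc[src, src] = rep.median_r
        for tgt in cells:
            if tgt == src:
                continue
            results = transfer_all_marks(matrices[src], matrices[tgt])
            out.loc[tgt, src] = float(np.median([t.r for t in results]))
    return out


def cluster_cell_lines(similarity: pd.DataFrame):
    """Average-linkage clustering of cell lines on d = 1 − symmetrized r.

    Returns (linkage matrix, leaf order as cell-line names).
    """
    s = similarity.to_numpy(dtype=float)
    if s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    names = list(similarity.index)
    if len(names) == 1:
        return np.empty((0, 4)), names
    sym = (s + s.T) / 2.0
    d = 1.0 - sym
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    Z = hierarchy.average(squareform(d, checks=False))
    order = hierarchy.leaves_list(Z)
    return Z, [names[i] for i in order]


def plot_similarity_heatmap(similarity: pd.DataFrame, ax=None):
    """Heatmap of the predictive-similarity matrix (targets = rows)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(similarity.to_numpy(dtype=float), vmin=-1, vmax=1,
                   cmap="RdBu_r")
    ax.set_xticks(range(len(similarity.columns)), similarity.columns,
                  rotation=90)
    ax.set_yticks(range(len(similarity.index)), similarity.index)
    ax.set_xlabel("source cell line")
    ax.set_ylabel("target cell line")
    ax.figure.colorbar(im, ax=ax, label="median Pearson r")
    return ax
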