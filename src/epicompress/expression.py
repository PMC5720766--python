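"""CAGE-based gene-expression quantification and modelling.

Expression per gene is read off strand-specific CAGE coverage as the summed
density of the two central 100-bp bins of the 40-bin TSS flank on both
strands: GEx = bin20(+) + bin21(+) + bin20(−) + bin21(−) (1-based bins), i.e.
the ±100 bp window around the TSS.  The modelled response is
gex = quantile-scaled ln(GEx + ε) for a pseudocount ε scanned over
{0.001, 0.01, 0.1, 1}.  Mark inputs come at three resolutions: the 1-bin
TSS value, all 40 bins, or only the middle two bins; models are linear or
additive MARS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import EnrichmentMatrix, quantile_scale
from .models import CVResult, fit_mars, fit_ols, kfold_cv, pearson_with_pvalue, predict
from .regions import RegionSet
from .tracks import SignalTrack, count_region_bins

__all__ = [
    "PSEUDOCOUNTS",
    "MIDDLE_BINS",
    "ExpressionModelSpec",
    "compute_cage_gex",
    "transform_gex",
    "build_expression_features",
    "fit_expression_cv",
    "scan_pseudocounts",
    "transfer_expression",
    "ExpressionModel",
    "ExpressionResults",
]

PSEUDOCOUNTS = (0.001, 0.01, 0.1, 1.0)
MIDDLE_BINS = (20, 21)  # 1-based; the ±100 bp window of a 40-bin 4-kb flank
VARIANTS = ("one_bin", "forty_bin", "middle_two")


@dataclass(frozen=True)
class ExpressionModelSpec:
    input_variant: str = "middle_two"
    model_type: str = "linear"  # linear | mars
    epsilon: float = 0.1
    cell_line: str = ""
    gene_type: str = "protein_coding"

    def __post_init__(self):
        if self.input_variant not in VARIANTS:
            raise ValueError(f"unknown input variant {self.input_variant!r}")
        if self.model_type not in ("linear", "mars"):
            raise ValueError(f"unknown model type {self.model_type!r}")
        if self.epsilon <= 0:
            raise ValueError("pseudocount must be positive")


def compute_cage_gex(
    plus: SignalTrack, minus: SignalTrack, tss_regions: RegionSet
) -> np.ndarray:
    """Raw GEx per gene from plus/minus CAGE coverage on 40-bin TSS flanks."""
    if tss_regions.n_bins != 40:
        raise ValueError("GEx is defined on 40-bin TSS regions")
    if plus is None or minus is None:
        raise ValueError("both strand tracks are required")
    b = [m - 1 for m in MIDDLE_BINS]
    gex = np.zeros(len(tss_regions))
    for track in (plus, minus):
        dens = count_region_bins(track, tss_regions)
        gex += dens[:, b].sum(axis=1)
    return gex


def transform_gex(raw: np.ndarray, epsilon: float, q: float = 0.01) -> np.ndarray:
    """gex = quantile-scaled natural log of (GEx + ε), in [0, 1]."""
    if epsilon <= 0:
        raise ValueError("pseudocount must be positive")
    return quantile_scale(np.log(np.asarray(raw, dtype=np.float64) + epsilon), q)


def build_expression_features(
    matrix: EnrichmentMatrix, variant: str
) -> tuple[np.ndarray, list[str]]:
    """Mark-input features at the requested resolution.

    Only the absolute methylation flavor enters expression models; the
    CpG-normalised column is dropped.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown input variant {variant!r}")
    if variant == "one_bin" and matrix.n_bins != 1:
        raise ValueError("one_bin variant needs a 1-bin matrix")
    if variant in ("forty_bin", "middle_two") and matrix.n_bins != 40:
        raise ValueError(f"{variant} variant needs a 40-bin matrix")
    keep = [
        i for i, m in enumerate(matrix.marks)
        if m.methylation_flavor != "cpg_normalized"
    ]
    B = matrix.n_bins
    cols, labels = [], []
    for i in keep:
        m = matrix.marks[i]
        if variant == "middle_two":
            bins = [b - 1 for b in MIDDLE_BINS]
        else:
            bins = list(range(B))
        cols.extend(i * B + b for b in bins)
        if B == 1:
            labels.append(m.column_name)
        else:
            labels.extend(f"{m.column_name}:bin{b + 1}" for b in bins)
    return matrix.values[:, cols], labels


def fit_expression_cv(
    features: np.ndarray,
    gex: np.ndarray,
    spec: ExpressionModelSpec,
    k: int = 10,
    seed: int | None = 0,
    **model_kwargs,
) -> CVResult:
    """10-fold-CV expression prediction for the given model spec."""
    model = "ols" if spec.model_type == "linear" else "mars"
    return kfold_cv(features, gex, k=k, model=model, seed=seed,
                    target=f"gex[{spec.input_variant},{spec.model_type}]",
                    **model_kwargs)


def scan_pseudocounts(
    features: np.ndarray,
    raw_gex: np.ndarray,
    spec: ExpressionModelSpec,
    pseudocounts=PSEUDOCOUNTS,
    k: int = 10,
    seed: int | None = 0,
    **model_kwargs,
) -> tuple[ExpressionModelSpec, pd.DataFrame]:
    """CV r for each pseudocount; returns (best spec, full scan table).

    Ties break to the smaller ε.
    """
    if not len(pseudocounts):
        raise ValueError("empty pseudocount grid")
    rows = []
    for eps in sorted(pseudocounts):
        gex = transform_gex(raw_gex, eps)
        res = fit_expression_cv(features, gex, spec, k=k, seed=seed,
                                **model_kwargs)
        rows.append({"variant": spec.input_variant, "model": spec.model_type,
                     "epsilon": eps, "r": res.pearson_r, "p": res.p_value})
    table = pd.DataFrame(rows)
    best_eps = float(table.loc[table["r"].idxmax(), "epsilon"])
    best = ExpressionModelSpec(
        input_variant=spec.input_variant, model_type=spec.model_type,
        epsilon=best_eps, cell_line=spec.cell_line, gene_type=spec.gene_type,
    )
    return best, table


def transfer_expression(
    features_a: np.ndarray,
    raw_gex_a: np.ndarray,
    features_b: np.ndarray,
    raw_gex_b: np.ndarray,
    spec: ExpressionModelSpec,
    **model_kwargs,
) -> tuple[float, float]:
    """Fit expression in cell line A on 100% of genes, evaluate in B.

    Features must already be restricted to the common marks; the same ε
    (the source-cell optimum, carried in ``spec``) is used to form gex on
    both sides.
    """
    gex_a = transform_gex(raw_gex_a, spec.epsilon)
    gex_b = transform_gex(raw_gex_b, spec.epsilon)
    if spec.model_type == "linear":
        fit = fit_ols(features_a, gex_a)
    else:
        fit = fit_mars(features_a, gex_a, **model_kwargs)
    return pearson_with_pvalue(gex_b, predict(fit, features_b))


# ---------------------------------------------------------------------------
# model-object surface


class ExpressionModel:
    """Expression model for one cell line / gene type.

    Built from a mark matrix at the spec's resolution and the raw GEx
    vector; ``fit()`` runs the pseudocount scan and the CV fit at the best
    ε and returns :class:`ExpressionResults`.
    """

    def __init__(
        self,
        matrix: EnrichmentMatrix,
        raw_gex: np.ndarray,
        variant: str = "middle_two",
        model_type: str = "linear",
    ):
        self.matrix = matrix
        self.raw_gex = np.asarray(raw_gex, dtype=np.float64)
        if self.raw_gex.size != matrix.n_genes:
            raise ValueError("GEx vector length != number of genes")
        self.spec = ExpressionModelSpec(
            input_variant=variant, model_type=model_type,
            cell_line=matrix.cell_line, gene_type=matrix.gene_type,
        )
        self.features, self.feature_labels = build_expression_features(
            matrix, variant
        )

    def fit(self, k: int = 10, seed: int | None = 0,
            pseudocounts=PSEUDOCOUNTS, **model_kwargs) -> "ExpressionResults":
        best, scan = scan_pseudocounts(
            self.features, self.raw_gex, self.spec, pseudocounts=pseudocounts,
            k=k, seed=seed, **model_kwargs,
        )
        gex = transform_gex(self.raw_gex, best.epsilon)
        cv = fit_expression_cv(self.features, gex, best, k=k, seed=seed,
                               **model_kwargs)
        if best.model_type == "linear":
            full = fit_ols(self.features, gex, columns=self.feature_labels)
        else:
            full = fit_mars(self.features, gex, columns=self.feature_labels,
                            **model_kwargs)
        return ExpressionResults(self, best, scan, cv, full, k=k, seed=seed)


class ExpressionResults:
    def __init__(self, model, spec, scan, cv, full_fit, k, seed):
        self.model = model
        self.spec = spec
        self.scan = scan
        self.cv = cv
        self.full_fit = full_fit
        self.k = k
        self.seed = seed

    @property
    def pearson_r(self) -> float:
        return self.cv.pearson_r

    @property
    def p_value(self) -> float:
        return self.cv.p_value

    def summary(self) -> str:
        lines = [
            f"Expression model ({self.spec.model_type}, "
            f"{self.spec.input_variant} input, {self.k}-fold CV, "
            f"seed={self.seed})",
            f"cell_line={self.spec.cell_line or '-'} "
            f"gene_type={self.spec.gene_type}",
            f"genes: {self.model.matrix.n_genes}   "
            f"features: {self.model.features.shape[1]}",
            f"best pseudocount: {self.spec.epsilon:g}",
            f"CV Pearson r: {self.pearson_r:.4f}   p: {self.p_value:.3g}",
            "",
            "pseudocount scan:",
            self.scan.to_string(index=False,
                                float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
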