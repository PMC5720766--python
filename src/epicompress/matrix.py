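"""Enrichment matrices: genes × (mark, bin) tables of scaled signal.

Each constellation (cell line, gene type, region type) yields one matrix.
Raw per-bin tag densities are quantile-scaled per mark — pooling all of a
mark's bins — so that values live in [0, 1] with the bottom q mass at 0 and
the top q at 1 (default q = 0.01, with q = 0.05 as the supported
alternative).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "MarkMeta",
    "EnrichmentMatrix",
    "quantile_scale",
    "assemble_matrix",
    "MARK_TYPES",
    "REGULATORY_TYPES",
]

MARK_TYPES = (
    "chromatin_remodeler",
    "coregulator",
    "epigenetic_mark",
    "transcription_factor",
    "other_nonregulatory",
)
# types with a known regulatory role; "other_nonregulatory" marks are kept in
# the models but excluded from type-overrepresentation statistics
REGULATORY_TYPES = MARK_TYPES[:4]


@dataclass(frozen=True)
class MarkMeta:
    mark_name: str
    mark_type: str = "epigenetic_mark"
    methylation_flavor: str = "none"  # none | absolute | cpg_normalized

    def __post_init__(self) -> None:
        if self.mark_type not in MARK_TYPES:
            raise ValueError(f"unknown mark_type {self.mark_type!r}")
        if self.methylation_flavor not in ("none", "absolute", "cpg_normalized"):
            raise ValueError(
                f"unknown methylation_flavor {self.methylation_flavor!r}"
            )

    @property
    def column_name(self) -> str:
        if self.methylation_flavor == "none":
            return self.mark_name
        return f"{self.mark_name}[{self.methylation_flavor}]"


class EnrichmentMatrix:
    """genes × (marks × bins) matrix of enrichment values in [0, 1].

    ``values`` is mark-major: columns [m0b0 … m0b(B-1), m1b0, …].
    """

    def __init__(
        self,
        values: np.ndarray,
        genes: list[str],
        marks: list[MarkMeta],
        n_bins: int = 1,
        cell_line: str = "",
        gene_type: str = "protein_coding",
        region_type: str = "tss_flank",
    ):
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (len(genes), len(marks) * n_bins):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"{len(genes)} genes × {len(marks)} marks × {n_bins} bins"
            )
        self.values = values
        self.genes = list(genes)
        self.marks = list(marks)
        self.n_bins = int(n_bins)
        self.cell_line = cell_line
        self.gene_type = gene_type
        self.region_type = region_type

    # -- introspection -------------------------------------------------
    @property
    def constellation(self) -> tuple[str, str, str]:
        return (self.cell_line, self.gene_type, self.region_type)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_marks(self) -> int:
        return len(self.marks)

    def mark_index(self, mark: str | MarkMeta) -> int:
        if isinstance(mark, MarkMeta):
            return self.marks.index(mark)
        names = [m.column_name for m in self.marks]
        if mark in names:
            return names.index(mark)
        plain = [m.mark_name for m in self.marks]
        if plain.count(mark) == 1:
            return plain.index(mark)
        if plain.count(mark) > 1:
            raise KeyError(
                f"mark {mark!r} is ambiguous (multiple methylation flavors); "
                "use the column name, e.g. 'DNAme[absolute]'"
            )
        raise KeyError(f"mark {mark!r} not in matrix")

    def mark_columns(self, mark: str | MarkMeta) -> slice:
        i = self.mark_index(mark)
        return slice(i * self.n_bins, (i + 1) * self.n_bins)

    def mark_values(self, mark: str | MarkMeta) -> np.ndarray:
        return self.values[:, self.mark_columns(mark)]

    def column_labels(self) -> list[str]:
        labels = []
        for m in self.marks:
            if self.n_bins == 1:
                labels.append(m.column_name)
            else:
                labels.extend(f"{m.column_name}:bin{b + 1}" for b in range(self.n_bins))
        return labels

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.column_labels())

    # -- manipulation --------------------------------------------------
    def subset_genes(self, gene_ids: list[str]) -> "EnrichmentMatrix":
        index = {g: i for i, g in enumerate(self.genes)}
        rows = [index[g] for g in gene_ids]
        return EnrichmentMatrix(
            self.values[rows], gene_ids, self.marks, self.n_bins,
            self.cell_line, self.gene_type, self.region_type,
        )

    def subset_marks(self, marks: list) -> "EnrichmentMatrix":
        idx = [self.mark_index(m) for m in marks]
        cols = np.concatenate(
            [np.arange(i * self.n_bins, (i + 1) * self.n_bins) for i in idx]
        )
        return EnrichmentMatrix(
            self.values[:, cols], self.genes, [self.marks[i] for i in idx],
            self.n_bins, self.cell_line, self.gene_type, self.region_type,
        )

    # -- persistence ---------------------------------------------------
    def to_tsv(self, path) -> None:
        """TSV of values plus a JSON sidecar (<path>.meta.json) of metadata."""
        df = self.to_dataframe()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.10g")
        meta = {
            "cell_line": self.cell_line,
            "gene_type": self.gene_type,
            "region_type": self.region_type,
            "n_bins": self.n_bins,
            "marks": [asdict(m) for m in self.marks],
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)

    @classmethod
    def from_tsv(cls, path) -> "EnrichmentMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        marks = [MarkMeta(**m) for m in meta["marks"]]
        return cls(
            df.to_numpy(dtype=np.float64), list(df.index.astype(str)), marks,
            meta["n_bins"], meta["cell_line"], meta["gene_type"],
            meta["region_type"],
        )


def quantile_scale(raw: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Clip at the q / (1−q) empirical quantiles and rescale linearly to [0, 1].

    All columns of ``raw`` are pooled (one mark's bins form one pool).
    Linear-interpolation quantiles.  A constant pool maps to all zeros with
    a warning.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    raw = np.asarray(raw, dtype=np.float64)
    lo = float(np.quantile(raw, q))
    hi = float(np.quantile(raw, 1 - q))
    if hi <= lo:
        warnings.warn("constant mark signal; scaled values set to 0")
        return np.zeros_like(raw)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


def assemble_matrix(
    per_mark_raw: list[np.ndarray],
    marks: list[MarkMeta],
    genes: list[str],
    n_bins: int = 1,
    q: float = 0.01,
    cell_line: str = "",
    gene_type: str = "protein_coding",
    region_type: str = "tss_flank",
    scaled: bool = False,
) -> EnrichmentMatrix:
    """Quantile-scale each mark's raw (genes × n_bins) block and glue them.

    ``scaled=True`` skips the scaling (blocks already in [0, 1]).
    """
    if len(per_mark_raw) != len(marks):
        raise ValueError("one raw block per mark required")
    blocks = []
    for block, meta in zip(per_mark_raw, marks):
        block = np.asarray(block, dtype=np.float64)
        if block.ndim == 1:
            block = block[:, None]
        if block.shape != (len(genes), n_bins):
            raise ValueError(
                f"mark {meta.column_name}: block shape {block.shape} != "
                f"({len(genes)}, {n_bins})"
            )
        blocks.append(block if scaled else quantile_scale(block, q))
    values = np.hstack(blocks) if blocks else np.zeros((len(genes), 0))
    return EnrichmentMatrix(
        values, genes, marks, n_bins, cell_line, gene_type, region_type
    )
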