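"""End-to-end construction of enrichment matrices from files on disk.

Glues the stages together: parse the annotation, derive and filter one
region type, count every mark track into bins, apply the methylation/CpG
normalisation, and quantile-scale per mark into an
:class:`~epicompress.matrix.EnrichmentMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import EnrichmentMatrix, MarkMeta, assemble_matrix
from .regions import (
    IntervalSet,
    derive_regions,
    filter_regions,
    parse_gene_annotation,
)
from .tracks import (
    count_cpgs,
    count_region_bins,
    cpg_positions,
    normalize_methylation,
    read_signal_track,
)

__all__ = ["TrackEntry", "build_matrix", "read_manifest"]


@dataclass(frozen=True)
class TrackEntry:
    mark_name: str
    path: str
    mark_type: str = "epigenetic_mark"
    format: str = "bedGraph"
    is_methylation: bool = False


def read_manifest(path) -> list[TrackEntry]:
    """Track manifest TSV: mark, path, [type], [format], [methylation 0/1]."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for _, row in df.iterrows():
        entries.append(TrackEntry(
            mark_name=str(row["mark"]),
            path=str(row["path"]),
            mark_type=str(row.get("type", "epigenetic_mark")),
            format=str(row.get("format", "bedGraph")),
            is_methylation=bool(int(row.get("methylation", 0))),
        ))
    return entries


def build_matrix(
    gtf_path,
    tracks: list[TrackEntry],
    gene_type: str = "protein_coding",
    region_type: str = "tss_flank",
    n_bins: int = 1,
    flank: int = 2000,
    q: float = 0.01,
    blacklist=None,
    excluded_chroms=("chrX", "chrY"),
    chrom_sizes: dict[str, int] | None = None,
    genome_fasta=None,
    cpg_bed=None,
    cell_line: str = "",
) -> EnrichmentMatrix:
    """Build one constellation's enrichment matrix from files.

    ``blacklist`` may be a BED path or an :class:`IntervalSet`.  Methylation
    tracks yield two matrix columns (absolute and CpG-normalised); a CpG
    source (FASTA or BED) is then required.
    """
    genes = parse_gene_annotation(gtf_path, gene_type)
    regions = derive_regions(genes, region_type, flank=flank, n_bins=n_bins,
                             chrom_sizes=chrom_sizes)
    if blacklist is not None and not isinstance(blacklist, IntervalSet):
        blacklist = IntervalSet.from_bed(blacklist)
    regions = filter_regions(regions, blacklist, excluded_chroms)
    gene_ids = regions.gene_ids()

    needs_cpg = any(t.is_methylation for t in tracks)
    cpg = None
    if needs_cpg:
        pos = cpg_positions(genome_fasta=genome_fasta, cpg_bed=cpg_bed)
        cpg = count_cpgs(regions, positions=pos)

    blocks, meta = [], []
    for entry in tracks:
        track = read_signal_track(entry.path, format=entry.format,
                                  mark_name=entry.mark_name,
                                  cell_line=cell_line)
        raw = count_region_bins(track, regions)
        if entry.is_methylation:
            blocks.append(raw)
            meta.append(MarkMeta(entry.mark_name, entry.mark_type, "absolute"))
            blocks.append(normalize_methylation(raw, cpg))
            meta.append(
                MarkMeta(entry.mark_name, entry.mark_type, "cpg_normalized")
            )
        else:
            blocks.append(raw)
            meta.append(MarkMeta(entry.mark_name, entry.mark_type))
    return assemble_matrix(
        blocks, meta, gene_ids, n_bins=n_bins, q=q, cell_line=cell_line,
        gene_type=gene_type, region_type=region_type,
    )
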