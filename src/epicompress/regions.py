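"""Gene annotations and the three per-gene region types.

A gene is summarised by its outermost TSS and TTS over all annotated
transcripts.  Three region types are derived per gene: a symmetric flank
around the TSS, the gene body (outermost TSS to outermost TTS), and a
symmetric flank around the TTS.  Regions can be cut into equal-width bins;
40-bin resolution is only defined for TSS flanks.

Coordinates: GTF input is 1-based inclusive and is converted once at parse
time; everything internal (and BED/bedGraph) is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneAnnotation",
    "RegionSet",
    "IntervalSet",
    "GtfParseError",
    "parse_gene_annotation",
    "derive_regions",
    "filter_regions",
    "GENE_TYPES",
    "REGION_TYPES",
]

GENE_TYPES = ("protein_coding", "lincRNA")
REGION_TYPES = ("tss_flank", "gene_body", "tts_flank")


class GtfParseError(ValueError):
    """Raised for a malformed GTF record, naming the offending line."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene with transcription-oriented outermost TSS/TTS.

    ``tss``/``tts`` are 0-based genomic positions: for a + strand gene the
    TSS is the minimal transcript start, for a − strand gene the maximal
    transcript end − 1 (the first transcribed base).
    """

    gene_id: str
    gene_type: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.strand == "+" and self.tss > self.tts:
            raise ValueError(f"+ strand gene {self.gene_id} has tss > tts")
        if self.strand == "-" and self.tts > self.tss:
            raise ValueError(f"- strand gene {self.gene_id} has tts > tss")

    @property
    def start(self) -> int:
        """Genomic start (lower coordinate) of the gene span."""
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        """Genomic end (exclusive upper coordinate) of the gene span."""
        return max(self.tss, self.tts) + 1


@dataclass(frozen=True)
class Region:
    gene_id: str
    chrom: str
    start: int  # clamped at 0
    end: int
    strand: str
    truncated: bool = False
    # untruncated coordinates anchor the bin grid so a clamped flank keeps
    # its nominal 2*flank/n_bins bin width, with out-of-range bins empty
    nominal_start: int = None  # type: ignore[assignment]
    nominal_end: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nominal_start is None:
            object.__setattr__(self, "nominal_start", self.start)
        if self.nominal_end is None:
            object.__setattr__(self, "nominal_end", self.end)


@dataclass
class RegionSet:
    """A set of equally-binned regions of one region type."""

    region_type: str
    flank: int
    n_bins: int
    entries: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.entries]

    def bin_edges(self, region: Region) -> np.ndarray:
        """Integer-valued bin edges over the nominal region span."""
        return np.linspace(region.nominal_start, region.nominal_end, self.n_bins + 1)


@dataclass
class IntervalSet:
    """Plain genomic intervals (e.g. a blacklist), 0-based half-open."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            by.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs], dtype=np.int64)
            ends = np.maximum.accumulate(np.array([e for _, e in ivs], dtype=np.int64))
            self._by_chrom[chrom] = (starts, ends)

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                f = line.split("\t")
                intervals.append((f[0], int(f[1]), int(f[2])))
        return cls(intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any interval by >= 1 bp."""
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        # candidate intervals starting before `end`; running-max ends make
        # a single comparison sufficient
        i = int(np.searchsorted(starts, end, side="left"))
        if i == 0:
            return False
        return bool(ends[i - 1] > start)


def _parse_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for item in attr_field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def parse_gene_annotation(gtf_path, gene_type: str) -> list[GeneAnnotation]:
    """Read a Gencode-style GTF and return one record per gene of ``gene_type``.

    The TSS is the transcription-orientation-most-upstream transcript start
    (minimal genomic start for +, maximal genomic end for −) over all
    transcripts of the gene; the TTS symmetrically.  Genes without any
    transcript record are omitted.
    """
    if gene_type not in GENE_TYPES:
        raise ValueError(
            f"unknown gene_type filter {gene_type!r}; expected one of {GENE_TYPES}"
        )
    # per gene: chrom, strand, min genomic start (0-based), max genomic end (excl)
    spans: dict[str, list] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields[:9]
            )
            if feature != "transcript":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-"):
                raise GtfParseError(f"{gtf_path}: line {lineno}: bad strand {strand!r}")
            attr = _parse_attributes(attrs)
            if "gene_id" not in attr:
                raise GtfParseError(f"{gtf_path}: line {lineno}: missing gene_id")
            if attr.get("gene_type") != gene_type:
                continue
            gid = attr["gene_id"]
            start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            rec = spans.get(gid)
            if rec is None:
                spans[gid] = [chrom, strand, start0, end0]
            else:
                if rec[0] != chrom or rec[1] != strand:
                    raise GtfParseError(
                        f"{gtf_path}: line {lineno}: gene {gid} spans chromosomes "
                        "or strands"
                    )
                rec[2] = min(rec[2], start0)
                rec[3] = max(rec[3], end0)
    genes = []
    for gid, (chrom, strand, start0, end0) in spans.items():
        if strand == "+":
            tss, tts = start0, end0 - 1
        else:
            tss, tts = end0 - 1, start0
        genes.append(
            GeneAnnotation(
                gene_id=gid, gene_type=gene_type, chrom=chrom, strand=strand,
                tss=tss, tts=tts,
            )
        )
    return genes


def derive_regions(
    genes: Sequence[GeneAnnotation],
    region_type: str,
    flank: int = 2000,
    n_bins: int = 1,
    chrom_sizes: dict[str, int] | None = None,
) -> RegionSet:
    """Derive one binned region per gene.

    tss_flank = [tss − flank, tss + flank), gene_body = genomic gene span,
    tts_flank = [tts − flank, tts + flank).  Regions reaching past a
    chromosome edge are clamped and flagged; their bin grid stays anchored
    on the nominal span so bin widths are unchanged.
    """
    if region_type not in REGION_TYPES:
        raise ValueError(f"unknown region_type {region_type!r}")
    if n_bins not in (1, 40):
        raise ValueError("n_bins must be 1 or 40")
    if n_bins == 40 and region_type != "tss_flank":
        raise ValueError("40-bin resolution is only defined for tss_flank regions")
    entries = []
    for g in genes:
        if region_type == "tss_flank":
            ns, ne = g.tss - flank, g.tss + flank
        elif region_type == "tts_flank":
            ns, ne = g.tts - flank, g.tts + flank
        else:
            ns, ne = g.start, g.end
        if region_type == "gene_body" and ne - ns <= 1:
            warnings.warn(f"gene {g.gene_id}: zero-length gene body dropped")
            continue
        start = max(ns, 0)
        end = ne
        size = None if chrom_sizes is None else chrom_sizes.get(g.chrom)
        if size is not None:
            end = min(ne, size)
        truncated = (start != ns) or (end != ne)
        if end <= start:
            warnings.warn(f"gene {g.gene_id}: region entirely out of bounds, dropped")
            continue
        entries.append(
            Region(
                gene_id=g.gene_id, chrom=g.chrom, start=start, end=end,
                strand=g.strand, truncated=truncated,
                nominal_start=ns, nominal_end=ne,
            )
        )
    return RegionSet(region_type=region_type, flank=flank, n_bins=n_bins,
                     entries=entries)


def filter_regions(
    regions: RegionSet,
    blacklist: IntervalSet | None = None,
    excluded_chroms: Iterable[str] = ("chrX", "chrY"),
    removed_log: dict[str, str] | None = None,
) -> RegionSet:
    """Drop regions overlapping the blacklist (>= 1 bp) or on excluded chromosomes.

    ``removed_log`` (optional dict) records gene_id -> reason.
    """
    excluded = set(excluded_chroms)
    kept = []
    for r in regions.entries:
        if r.chrom in excluded:
            if removed_log is not None:
                removed_log[r.gene_id] = f"excluded chromosome {r.chrom}"
            continue
        if blacklist is not None and blacklist.overlaps(r.chrom, r.start, r.end):
            if removed_log is not None:
                removed_log[r.gene_id] = "blacklist overlap"
            continue
        kept.append(r)
    return RegionSet(region_type=regions.region_type, flank=regions.flank,
                     n_bins=regions.n_bins, entries=kept)
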