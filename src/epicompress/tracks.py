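"""Signal tracks (bedGraph / wig) and binned tag counting.

A track is stored as sorted, non-overlapping runs (start, end, value) per
chromosome.  "Tags" are treated as signal mass — run value × covered bp —
so raw tag-count tracks and pre-computed coverage tracks are handled
identically.  Bin entries are mass divided by bin width (tag density), the
bin-size normalisation needed because gene bodies vary in length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .regions import IntervalSet, RegionSet

__all__ = [
    "SignalTrack",
    "read_signal_track",
    "write_bedgraph",
    "count_region_bins",
    "count_cpgs",
    "normalize_methylation",
]


@dataclass
class SignalTrack:
    mark_name: str = ""
    cell_line: str = ""
    # chrom -> (starts, ends, values) arrays, sorted, non-overlapping
    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def chroms(self) -> list[str]:
        return list(self.runs)

    def total_mass(self, chrom: str | None = None) -> float:
        chroms = [chrom] if chrom is not None else self.chroms()
        mass = 0.0
        for c in chroms:
            s, e, v = self.runs[c]
            mass += float(np.sum((e - s) * v))
        return mass


def _finalize_runs(
    raw: dict[str, list[tuple[int, int, float]]], path, absolute_values: bool
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    runs = {}
    for chrom, entries in raw.items():
        starts = np.array([s for s, _, _ in entries], dtype=np.int64)
        ends = np.array([e for _, e, _ in entries], dtype=np.int64)
        values = np.array([v for _, _, v in entries], dtype=np.float64)
        order = np.argsort(starts, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            warnings.warn(f"{path}: runs on {chrom} were unsorted; sorting")
            starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{path}: overlapping runs on {chrom}")
        if absolute_values:
            values = np.abs(values)
        elif np.any(values < 0):
            raise ValueError(f"{path}: negative signal value on {chrom}")
        runs[chrom] = (starts, ends, values)
    return runs


def read_signal_track(
    path,
    format: str = "bedGraph",
    mark_name: str = "",
    cell_line: str = "",
    absolute_values: bool = False,
) -> SignalTrack:
    """Read a bedGraph or (fixed/variable-step) wig file into runs.

    ``absolute_values`` takes |value| on read — used for minus-strand CAGE
    coverage, which is sometimes emitted with negative sign.
    """
    if format == "bigwig":
        return _read_bigwig(path, mark_name, cell_line)
    if format not in ("bedGraph", "wig"):
        raise ValueError(f"unknown track format {format!r}")
    raw: dict[str, list[tuple[int, int, float]]] = {}
    # wig parser state
    mode = None  # "fixed" | "variable"
    chrom = None
    pos = span = step = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            if format == "bedGraph":
                f = line.split("\t") if "\t" in line else line.split()
                if len(f) < 4:
                    raise ValueError(f"{path}: line {lineno}: bad bedGraph record")
                c, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
                if e <= s:
                    raise ValueError(f"{path}: line {lineno}: empty interval")
                raw.setdefault(c, []).append((s, e, v))
                continue
            if line.startswith("fixedStep"):
                opts = dict(kv.split("=") for kv in line.split()[1:])
                mode, chrom = "fixed", opts["chrom"]
                pos = int(opts["start"]) - 1  # wig is 1-based
                step = int(opts.get("step", 1))
                span = int(opts.get("span", step))
                continue
            if line.startswith("variableStep"):
                opts = dict(kv.split("=") for kv in line.split()[1:])
                mode, chrom = "variable", opts["chrom"]
                span = int(opts.get("span", 1))
                continue
            if mode is None:
                raise ValueError(f"{path}: line {lineno}: wig data before header")
            if mode == "fixed":
                v = float(line)
                raw.setdefault(chrom, []).append((pos, pos + span, v))
                pos += step
            else:
                f = line.split()
                start = int(f[0]) - 1
                raw.setdefault(chrom, []).append((start, start + span, float(f[1])))
    track = SignalTrack(mark_name=mark_name, cell_line=cell_line)
    track.runs = _finalize_runs(raw, path, absolute_values)
    return track


def _read_bigwig(path, mark_name, cell_line) -> SignalTrack:
    import pyBigWig

    bw = pyBigWig.open(str(path))
    raw: dict[str, list[tuple[int, int, float]]] = {}
    try:
        for chrom in bw.chroms():
            for s, e, v in bw.intervals(chrom) or []:
                raw.setdefault(chrom, []).append((int(s), int(e), float(v)))
    finally:
        bw.close()
    track = SignalTrack(mark_name=mark_name, cell_line=cell_line)
    track.runs = _finalize_runs(raw, path, absolute_values=False)
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write runs as bedGraph, skipping zero-value runs."""
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def count_region_bins(track: SignalTrack, regions: RegionSet) -> np.ndarray:
    """Overlap-weighted tag density per region bin.

    Returns an array of shape (n_regions, n_bins) with
    entry = Σ_runs value · |run ∩ bin| / bin_width.  Regions on chromosomes
    absent from the track yield zeros with a warning.
    """
    n_bins = regions.n_bins
    out = np.zeros((len(regions), n_bins), dtype=np.float64)
    missing: set[str] = set()
    for i, region in enumerate(regions.entries):
        if region.chrom not in track.runs:
            missing.add(region.chrom)
            continue
        starts, ends, values = track.runs[region.chrom]
        edges = regions.bin_edges(region)
        lo, hi = edges[0], edges[-1]
        # runs overlapping [lo, hi)
        j0 = int(np.searchsorted(ends, lo, side="right"))
        j1 = int(np.searchsorted(starts, hi, side="left"))
        if j1 <= j0:
            continue
        s = starts[j0:j1].astype(np.float64)
        e = ends[j0:j1].astype(np.float64)
        v = values[j0:j1]
        bin_w = (edges[-1] - edges[0]) / n_bins
        if n_bins == 1:
            overlap = np.minimum(e, hi) - np.maximum(s, lo)
            out[i, 0] = float(np.sum(v * np.clip(overlap, 0, None))) / bin_w
        else:
            cs = np.clip(s, lo, hi)
            ce = np.clip(e, lo, hi)
            b0 = np.floor((cs - lo) / bin_w).astype(np.int64)
            b1 = np.ceil((ce - lo) / bin_w).astype(np.int64)
            for rs, re_, rv, a, b in zip(cs, ce, v, b0, b1):
                if re_ <= rs:
                    continue
                b = min(b, n_bins)
                for k in range(a, b):
                    ov = min(re_, edges[k + 1]) - max(rs, edges[k])
                    if ov > 0:
                        out[i, k] += rv * ov / bin_w
    for chrom in missing:
        warnings.warn(f"chromosome {chrom} absent from track; zeros returned")
    return out


def _cpg_positions_from_sequence(seq: str) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide (forward strand)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(
        np.int64
    )


def cpg_positions(genome_fasta=None, cpg_bed=None) -> dict[str, np.ndarray]:
    """CpG C-positions per chromosome, from a FASTA or a precomputed BED."""
    if (genome_fasta is None) == (cpg_bed is None):
        raise ValueError("provide exactly one of genome_fasta or cpg_bed")
    pos: dict[str, np.ndarray] = {}
    if genome_fasta is not None:
        from pyfaidx import Fasta

        fa = Fasta(str(genome_fasta))
        for name in fa.keys():
            pos[name] = _cpg_positions_from_sequence(str(fa[name][:]))
    else:
        by: dict[str, list[int]] = {}
        iv = cpg_bed if isinstance(cpg_bed, IntervalSet) else IntervalSet.from_bed(cpg_bed)
        for chrom, start, _end in iv.intervals:
            by.setdefault(chrom, []).append(start)
        pos = {c: np.array(sorted(p), dtype=np.int64) for c, p in by.items()}
    return pos


def count_cpgs(
    regions: RegionSet,
    genome_fasta=None,
    cpg_bed=None,
    positions: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Integer CpG counts per region bin.

    A CpG is the dinucleotide CG on the forward strand and is assigned to
    the bin containing its C.
    """
    if positions is None:
        positions = cpg_positions(genome_fasta=genome_fasta, cpg_bed=cpg_bed)
    out = np.zeros((len(regions), regions.n_bins), dtype=np.int64)
    for i, region in enumerate(regions.entries):
        if region.chrom not in positions:
            raise KeyError(f"no sequence/CpG data for chromosome {region.chrom}")
        p = positions[region.chrom]
        edges = regions.bin_edges(region)
        counts, _ = np.histogram(p, bins=edges)
        # histogram's closed right edge on the last bin would include a C at
        # nominal_end; the region is half-open, so drop it
        if p.size and counts.size and np.any(p == edges[-1]):
            counts[-1] -= int(np.sum(p == edges[-1]))
        out[i] = counts
    return out


def normalize_methylation(meth: np.ndarray, cpg: np.ndarray) -> np.ndarray:
    """Per-bin methylation density divided by CpG count; 0 where no CpGs."""
    if meth.shape != cpg.shape:
        raise ValueError("methylation and CpG matrices must have the same shape")
    out = np.zeros_like(meth, dtype=np.float64)
    nz = cpg > 0
    out[nz] = meth[nz] / cpg[nz]
    return out
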