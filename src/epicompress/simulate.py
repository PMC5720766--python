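"""Synthetic multi-cell-line worlds with planted correlation structure.

The generator emulates the statistical skeleton of consortium epigenome
data so that every pipeline stage has checkable ground truth:

* per cell line, each gene carries a latent regulatory state ``z`` (iid
  standard normal) split into a *shared-program* block and a
  *cell-specific-program* block;
* each mark reads out the latent state through a sparse unit-norm loading
  vector plus Gaussian noise — marks with ``rule_class='shared'``
  ("activating-like") reuse their loadings in every cell line and load on
  the shared block; marks with ``rule_class='cell_specific'``
  ("silencing-like") load on the specific block with loadings resampled per
  cell line (constrained to pairwise cosine < 0.5 across cell lines so the
  planted dichotomy is identifiable);
* noise is calibrated so the best *achievable* cross-mark prediction r
  equals ``target_r``:  with M informative marks on an L-dimensional block,
  sigma^2 = (1 - r^2) / (r^2 + L/(M-1));
* signal is shaped into 100-bp bin-level coverage over the ±2 kb TSS flank,
  either flat across bins or concentrated at the promoter center with a
  gene-level background confound in the flanking bins;
* ln-expression is a (linear or hinge) function of the observed near-TSS
  mark levels plus noise, emitted as strand-split CAGE coverage in the two
  central bins;
* optionally a DNA-methylation mark with CpG-density-coupled signal, a
  blacklist overlapping a known fraction of genes, and a sex-chromosome
  gene subset exercise the filtering rules.

Everything is reproducible bit-for-bit from (config, seed); track values
are rounded to 6 decimals so that written files and in-memory matrices
agree exactly.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .matrix import EnrichmentMatrix, MarkMeta, assemble_matrix
from .regions import GeneAnnotation, IntervalSet

__all__ = [
    "MarkSpec",
    "ExpressionSpec",
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "world_report",
    "noise_sd_for_target_r",
]

_TYPE_CYCLE = (
    "epigenetic_mark",
    "transcription_factor",
    "coregulator",
    "chromatin_remodeler",
)


def noise_sd_for_target_r(target_r: float, latent_dim: int, n_marks: int) -> float:
    """Noise sd for unit-norm loadings such that the achievable CV r ≈ target_r.

    Accounts for latent-estimation error from the (n_marks − 1) noisy
    predictor marks spanning a latent block of dimension latent_dim.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    r2 = target_r**2
    if n_marks < 2:
        # single mark: no cross-mark prediction; fall back to the oracle form
        return float(np.sqrt((1 - r2) / r2))
    var = (1 - r2) / (r2 + latent_dim / (n_marks - 1))
    return float(np.sqrt(var))


@dataclass(frozen=True)
class MarkSpec:
    name: str
    mark_type: str = "epigenetic_mark"
    rule_class: str = "shared"  # shared | cell_specific
    is_methylation: bool = False

    def __post_init__(self):
        if self.rule_class not in ("shared", "cell_specific"):
            raise ValueError(f"unknown rule_class {self.rule_class!r}")


@dataclass(frozen=True)
class ExpressionSpec:
    link: str = "linear"  # linear | hinge
    coefs: tuple = ()  # ((mark_name, weight), ...); default set by config
    hinge_knot: float = 0.0
    target_r: float = 0.9
    fraction_silent: float = 0.05
    log_mean: float = 3.0
    log_sd: float = 1.5

    def __post_init__(self):
        if self.link not in ("linear", "hinge"):
            raise ValueError(f"unknown expression link {self.link!r}")


@dataclass
class WorldConfig:
    n_genes: int = 2000
    n_cell_lines: int = 2
    marks: list[MarkSpec] = field(default_factory=list)
    latent_dim: int = 6  # shared-program block
    latent_dim_specific: int = 4  # cell-specific-program block
    loading_sparsity: float = 0.5
    target_r: float = 0.9
    signal_profile: str = "flat"  # flat | promoter
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    include_methylation: bool = False
    cpg_density_range: tuple = (0.02, 0.12)
    blacklist_fraction: float = 0.02
    sex_chrom_fraction: float = 0.02
    lincRNA_fraction: float = 0.1
    genes_per_chrom: int = 250
    flank: int = 2000
    hub_mark: str | None = None
    hub_alignment: float = 0.85
    hub_noise_sd: float = 0.15
    baseline_level: float = 5.0
    amplitude: float = 1.2
    bin_jitter_sd: float = 0.05
    background_sd: float = 1.0  # promoter mode: flank-bin confound, in amp units
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_cell_lines < 1:
            raise ValueError("need at least one cell line")
        if not self.marks:
            raise ValueError("world config declares no marks")
        if self.signal_profile not in ("flat", "promoter"):
            raise ValueError(f"unknown signal_profile {self.signal_profile!r}")
        names = [m.name for m in self.marks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate mark names")
        if self.hub_mark is not None and self.hub_mark not in names:
            raise ValueError(f"hub mark {self.hub_mark!r} not among marks")
        if not 0 < self.loading_sparsity <= 1:
            raise ValueError("loading_sparsity must be in (0, 1]")

    @property
    def cell_lines(self) -> list[str]:
        return [f"cell{chr(ord('A') + i)}" for i in range(self.n_cell_lines)]

    # ------------------------------------------------------------------
    # presets: the standard study conditions
    @classmethod
    def imputation_world(cls, n_genes: int = 2000, n_marks: int = 20,
                         target_r: float = 0.9, n_cell_lines: int = 1,
                         seed: int = 0, **kw) -> "WorldConfig":
        """Planted linear structure: all marks share one program."""
        marks = [
            MarkSpec(f"MK{i + 1:02d}", _TYPE_CYCLE[i % 4], "shared")
            for i in range(n_marks)
        ]
        return cls(n_genes=n_genes, n_cell_lines=n_cell_lines, marks=marks,
                   latent_dim=3, target_r=target_r, seed=seed, **kw)

    @classmethod
    def transfer_world(cls, n_genes: int = 1000, n_shared: int = 10,
                       n_specific: int = 5, n_cell_lines: int = 3,
                       target_r: float = 0.9, seed: int = 0, **kw) -> "WorldConfig":
        """Shared-rule ("activating") vs cell-specific ("silencing") marks."""
        marks = [
            MarkSpec(f"ACT{i + 1:02d}", _TYPE_CYCLE[i % 4], "shared")
            for i in range(n_shared)
        ] + [
            MarkSpec(f"SIL{i + 1:02d}", "epigenetic_mark", "cell_specific")
            for i in range(n_specific)
        ]
        return cls(n_genes=n_genes, n_cell_lines=n_cell_lines, marks=marks,
                   latent_dim=4, latent_dim_specific=4, target_r=target_r,
                   seed=seed, **kw)

    @classmethod
    def hub_world(cls, n_marks: int = 8, n_genes: int = 600,
                  target_r: float = 0.9, seed: int = 0, **kw) -> "WorldConfig":
        """One high-information hub mark drives the dominant program."""
        marks = [
            MarkSpec(f"MK{i + 1:02d}", _TYPE_CYCLE[i % 4], "shared")
            for i in range(n_marks)
        ]
        # high-dimensional residual space keeps non-hub marks from pairing
        # up by chance, so the hub's information dominance is unambiguous
        return cls(n_genes=n_genes, n_cell_lines=1, marks=marks, latent_dim=8,
                   target_r=target_r, hub_mark="MK01", hub_noise_sd=0.1,
                   seed=seed, **kw)

    @classmethod
    def expression_world(cls, n_genes: int = 1200, n_marks: int = 8,
                         link: str = "linear", target_r: float = 0.9,
                         n_cell_lines: int = 1, seed: int = 0,
                         **kw) -> "WorldConfig":
        """Promoter-concentrated signal driving (ln) expression."""
        marks = [
            MarkSpec(f"MK{i + 1:02d}", _TYPE_CYCLE[i % 4], "shared")
            for i in range(n_marks)
        ]
        if link == "hinge":
            coefs = (("MK01", 1.0),)
        else:
            coefs = (("MK01", 1.0), ("MK02", 0.7), ("MK03", -0.5))
        expr = ExpressionSpec(link=link, coefs=coefs, target_r=target_r)
        return cls(n_genes=n_genes, n_cell_lines=n_cell_lines, marks=marks,
                   latent_dim=3, target_r=target_r, signal_profile="promoter",
                   expression=expr, seed=seed, **kw)


# ---------------------------------------------------------------------------


_N_BINS = 40  # tracks are synthesized at 100-bp bins over the 4-kb TSS flank


@dataclass
class WorldTruth:
    """Ground truth of a generated world (arrays live on the world object)."""

    config: WorldConfig
    mark_noise_sd: dict[str, float]
    theoretical_r: dict[str, float]
    loading_similarity: dict[str, float]  # mark -> min pairwise cosine across cells
    expected_first_selection: str
    n_blacklisted: int
    n_sex_chrom: int


class SyntheticWorld:
    """All in-memory state of one generated world.

    The heavy arrays are attributes: ``genes`` (gene table), ``m[cell]``
    (genes × marks observed mark levels), ``bin_values[cell][mark]``
    (genes × 40 rounded track bin values), ``gex[cell]`` (raw GEx).
    """

    def __init__(self, config: WorldConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self._build_genes()
        self._build_loadings()
        self._build_signal()
        self._build_expression()
        if config.include_methylation:
            self._build_methylation()
        self._build_blacklist()
        self.truth = self._make_truth()

    # -- gene layout ---------------------------------------------------
    def _build_genes(self):
        cfg = self.config
        rng = self.rng
        slot = 14_000
        n_sex = int(round(cfg.sex_chrom_fraction * cfg.n_genes))
        n_auto = cfg.n_genes - n_sex
        n_chroms = max(1, int(np.ceil(n_auto / cfg.genes_per_chrom)))
        genes = []
        lincs = rng.random(cfg.n_genes) < cfg.lincRNA_fraction
        strands = rng.choice(["+", "-"], size=cfg.n_genes)
        lengths = (rng.integers(20, 81, size=cfg.n_genes) * 100).astype(int)
        n_tx = rng.integers(1, 4, size=cfg.n_genes)
        for i in range(cfg.n_genes):
            if i < n_auto:
                chrom = f"chr{i // cfg.genes_per_chrom + 1}"
                pos = i % cfg.genes_per_chrom
            else:
                chrom = "chrX"
                pos = i - n_auto
            start = pos * slot + 4000
            end = start + int(lengths[i])
            strand = strands[i]
            tss = start if strand == "+" else end - 1
            tts = end - 1 if strand == "+" else start
            # nested extra transcripts (never outermost)
            txs = [(start, end)]
            for _ in range(int(n_tx[i]) - 1):
                off5 = int(rng.integers(0, lengths[i] // 4))
                off3 = int(rng.integers(0, lengths[i] // 4))
                txs.append((start + off5, end - off3))
            genes.append({
                "gene_id": f"G{i + 1:05d}",
                "gene_type": "lincRNA" if lincs[i] else "protein_coding",
                "chrom": chrom, "strand": strand, "start": start, "end": end,
                "tss": tss, "tts": tts, "transcripts": txs,
            })
        self.genes = genes
        self.chrom_sizes = {}
        for g in genes:
            need = g["end"] + 4000
            self.chrom_sizes[g["chrom"]] = max(
                self.chrom_sizes.get(g["chrom"], 0), need
            )

    # -- loadings and noise --------------------------------------------
    def _sparse_unit(self, rng, dim: int) -> np.ndarray:
        k = max(2, int(round(self.config.loading_sparsity * dim)))
        k = min(k, dim)
        support = rng.choice(dim, size=k, replace=False)
        w = np.zeros(dim)
        w[support] = rng.standard_normal(k)
        n = np.linalg.norm(w)
        if n == 0:
            w[support[0]] = 1.0
            n = 1.0
        return w / n

    def _build_loadings(self):
        cfg = self.config
        rng = self.rng
        shared = [m for m in cfg.marks if m.rule_class == "shared"]
        specific = [m for m in cfg.marks if m.rule_class == "cell_specific"]
        L_sh, L_sp = cfg.latent_dim, cfg.latent_dim_specific
        self.latent_dim_total = L_sh + L_sp
        self.mark_noise_sd = {}
        sd_sh = noise_sd_for_target_r(cfg.target_r, L_sh, max(len(shared), 2))
        sd_sp = noise_sd_for_target_r(cfg.target_r, L_sp, max(len(specific), 2))
        # loadings[cell][mark name] -> vector in the full latent space
        self.loadings: dict[str, dict[str, np.ndarray]] = {
            c: {} for c in cfg.cell_lines
        }
        hub = cfg.hub_mark
        for m in shared:
            if hub is not None:
                w = np.zeros(self.latent_dim_total)
                if m.name == hub:
                    w[0] = 1.0
                    sd = cfg.hub_noise_sd
                else:
                    a = cfg.hub_alignment
                    u = self._sparse_unit(rng, L_sh - 1)
                    w[0] = a
                    w[1:L_sh] = np.sqrt(1 - a**2) * u
                    sd = sd_sh
            else:
                w = np.zeros(self.latent_dim_total)
                w[:L_sh] = self._sparse_unit(rng, L_sh)
                sd = sd_sh
            for c in cfg.cell_lines:
                self.loadings[c][m.name] = w
            self.mark_noise_sd[m.name] = sd
        for m in specific:
            drawn: list[np.ndarray] = []
            for c in cfg.cell_lines:
                for _ in range(200):
                    u = self._sparse_unit(rng, L_sp)
                    if all(abs(u @ v) < 0.5 for v in drawn):
                        break
                else:
                    warnings.warn(
                        f"could not decorrelate loadings for {m.name}"
                    )
                drawn.append(u)
                w = np.zeros(self.latent_dim_total)
                w[L_sh:] = u
                self.loadings[c][m.name] = w
            self.mark_noise_sd[m.name] = sd_sp

    # -- signal --------------------------------------------------------
    def _build_signal(self):
        cfg = self.config
        rng = self.rng
        n, M = cfg.n_genes, len(cfg.marks)
        self.latent: dict[str, np.ndarray] = {}
        self.m: dict[str, np.ndarray] = {}
        self.background: dict[str, np.ndarray] = {}
        self.bin_values: dict[str, dict[str, np.ndarray]] = {}
        if cfg.signal_profile == "promoter":
            profile = np.zeros(_N_BINS)
            profile[16:24] = [0.25, 0.5, 0.75, 1.0, 1.0, 0.75, 0.5, 0.25]
            flank_mask = profile == 0
        else:
            profile = np.ones(_N_BINS)
            flank_mask = np.zeros(_N_BINS, dtype=bool)
        for c in cfg.cell_lines:
            z = rng.standard_normal((n, self.latent_dim_total))
            self.latent[c] = z
            W = np.column_stack([self.loadings[c][m.name] for m in cfg.marks])
            noise = rng.standard_normal((n, M)) * np.array(
                [self.mark_noise_sd[m.name] for m in cfg.marks]
            )
            mv = z @ W + noise
            self.m[c] = mv
            bg = rng.standard_normal((n, M)) * cfg.background_sd
            self.background[c] = bg
            bins = {}
            for j, mspec in enumerate(cfg.marks):
                jitter = rng.standard_normal((n, _N_BINS)) * cfg.bin_jitter_sd
                vals = (
                    cfg.baseline_level
                    + cfg.amplitude * mv[:, j][:, None] * profile[None, :]
                    + cfg.amplitude * bg[:, j][:, None] * flank_mask[None, :]
                    + cfg.amplitude * jitter
                )
                bins[mspec.name] = np.round(np.maximum(vals, 0.0), 6)
            self.bin_values[c] = bins

    # -- expression ----------------------------------------------------
    def _expression_coefs(self) -> list[tuple[str, float]]:
        cfg = self.config
        if cfg.expression.coefs:
            return [(n, float(w)) for n, w in cfg.expression.coefs]
        names = [m.name for m in cfg.marks[: min(3, len(cfg.marks))]]
        default = [1.0, 0.7, -0.5][: len(names)]
        return list(zip(names, default))

    def _build_expression(self):
        cfg = self.config
        rng = self.rng
        es = cfg.expression
        names = [m.name for m in cfg.marks]
        coefs = self._expression_coefs()
        self.activity: dict[str, np.ndarray] = {}
        self.gex: dict[str, np.ndarray] = {}
        self.cage_plus_fraction: dict[str, np.ndarray] = {}
        for c in cfg.cell_lines:
            act = np.zeros(cfg.n_genes)
            for name, w in coefs:
                x = self.m[c][:, names.index(name)]
                if es.link == "hinge":
                    x = np.maximum(0.0, x - es.hinge_knot)
                act = act + w * x
            self.activity[c] = act
            sd = float(np.std(act))
            noise_sd = sd * np.sqrt(1 / es.target_r**2 - 1)
            y = act + rng.standard_normal(cfg.n_genes) * noise_sd
            y = (y - np.mean(y)) / max(np.std(y), 1e-12)
            ln_gex = es.log_mean + es.log_sd * y
            gex = np.exp(ln_gex)
            floor = np.quantile(gex, es.fraction_silent)
            gex = np.round(np.maximum(gex - floor, 0.0), 6)
            self.gex[c] = gex
            self.cage_plus_fraction[c] = np.round(rng.beta(5, 5, cfg.n_genes), 6)

    # -- methylation ---------------------------------------------------
    def _build_methylation(self):
        cfg = self.config
        rng = self.rng
        lo, hi = cfg.cpg_density_range
        dens = rng.uniform(lo, hi, cfg.n_genes)
        self.cpg_positions: dict[str, np.ndarray] = {}
        per_chrom: dict[str, list[np.ndarray]] = {}
        self.cpg_bin_counts = np.zeros((cfg.n_genes, _N_BINS), dtype=np.int64)
        for i, g in enumerate(self.genes):
            lo_pos = g["tss"] - cfg.flank
            # CpGs on an even grid at the gene's density across its TSS flank
            step = max(2, int(round(2.0 / dens[i])) // 2 * 2)
            pos = np.arange(lo_pos, g["tss"] + cfg.flank - 1, step, dtype=np.int64)
            per_chrom.setdefault(g["chrom"], []).append(pos)
            rel = pos - lo_pos
            self.cpg_bin_counts[i] = np.bincount(rel // 100, minlength=_N_BINS)
        self.cpg_positions = {
            c: np.sort(np.concatenate(p)) for c, p in per_chrom.items()
        }
        # methylated fraction follows the methylation mark's latent level
        meth_marks = [m.name for m in cfg.marks if m.is_methylation]
        self.meth_fraction: dict[str, np.ndarray] = {}
        names = [m.name for m in cfg.marks]
        for c in cfg.cell_lines:
            if meth_marks:
                level = self.m[c][:, names.index(meth_marks[0])]
            else:
                level = rng.standard_normal(cfg.n_genes)
            self.meth_fraction[c] = np.round(
                np.clip(0.5 + 0.25 * level, 0.0, 1.0), 6
            )

    # -- blacklist ------------------------------------------------------
    def _build_blacklist(self):
        cfg = self.config
        rng = self.rng
        auto = [g for g in self.genes if g["chrom"] != "chrX"]
        n_bl = int(round(cfg.blacklist_fraction * len(auto)))
        picked = rng.choice(len(auto), size=n_bl, replace=False) if n_bl else []
        self.blacklist = []
        self.blacklisted_genes = set()
        for idx in sorted(picked):
            g = auto[idx]
            self.blacklist.append((g["chrom"], g["tss"] + 500, g["tss"] + 700))
            self.blacklisted_genes.add(g["gene_id"])

    # -- truth summary ---------------------------------------------------
    def _expected_first_selection(self) -> str:
        cfg = self.config
        cell = cfg.cell_lines[0]
        names = [m.name for m in cfg.marks]
        W = np.column_stack([self.loadings[cell][n] for n in names])
        sd = np.array([self.mark_noise_sd[n] for n in names])
        tot = np.sqrt(1.0 + sd**2)
        corr = (W.T @ W) / np.outer(tot, tot)
        med = []
        for j in range(len(names)):
            others = np.abs(np.delete(corr[j], j))
            med.append(np.median(others))
        return names[int(np.argmax(med))]

    def _make_truth(self) -> WorldTruth:
        cfg = self.config
        theo = {}
        shared = [m for m in cfg.marks if m.rule_class == "shared"]
        specific = [m for m in cfg.marks if m.rule_class == "cell_specific"]
        for m in cfg.marks:
            group = shared if m.rule_class == "shared" else specific
            L = cfg.latent_dim if m.rule_class == "shared" else cfg.latent_dim_specific
            sd = self.mark_noise_sd[m.name]
            delta = sd**2 * L / max(len(group) - 1, 1)
            theo[m.name] = float(np.sqrt(max(1 - delta, 0) / (1 + sd**2)))
        sim = {}
        for m in cfg.marks:
            cos = [
                float(self.loadings[a][m.name] @ self.loadings[b][m.name])
                for i, a in enumerate(cfg.cell_lines)
                for b in cfg.cell_lines[i + 1:]
            ]
            sim[m.name] = min(cos) if cos else 1.0
        return WorldTruth(
            config=cfg,
            mark_noise_sd=dict(self.mark_noise_sd),
            theoretical_r=theo,
            loading_similarity=sim,
            expected_first_selection=self._expected_first_selection(),
            n_blacklisted=len(self.blacklisted_genes),
            n_sex_chrom=sum(1 for g in self.genes if g["chrom"] == "chrX"),
        )

    # ------------------------------------------------------------------
    # analysis-ready objects (identical to the file pipeline's output)

    def analysis_genes(self, gene_type: str = "protein_coding") -> list[int]:
        """Indices of genes surviving blacklist and sex-chromosome filters."""
        return [
            i for i, g in enumerate(self.genes)
            if g["gene_type"] == gene_type
            and g["chrom"] != "chrX"
            and g["gene_id"] not in self.blacklisted_genes
        ]

    def mark_meta(self) -> list[MarkMeta]:
        meta = []
        for m in self.config.marks:
            if m.is_methylation:
                meta.append(MarkMeta(m.name, m.mark_type, "absolute"))
                meta.append(MarkMeta(m.name, m.mark_type, "cpg_normalized"))
            else:
                meta.append(MarkMeta(m.name, m.mark_type))
        return meta

    def enrichment_matrix(
        self,
        cell_line: str,
        n_bins: int = 1,
        gene_type: str = "protein_coding",
        q: float = 0.01,
    ) -> EnrichmentMatrix:
        """Quantile-scaled enrichment matrix straight from the planted bins."""
        rows = self.analysis_genes(gene_type)
        genes = [self.genes[i]["gene_id"] for i in rows]
        blocks, meta = [], []
        for mspec in self.config.marks:
            bv = self.bin_values[cell_line][mspec.name][rows]
            raw = bv.mean(axis=1, keepdims=True) if n_bins == 1 else bv
            if mspec.is_methylation:
                # mirror the file pipeline exactly: per-bin track value is
                # round(meth_fraction * cpg_count, 6); densities aggregate it
                cpg = self.cpg_bin_counts[rows]
                meth = np.round(
                    self.meth_fraction[cell_line][rows][:, None] * cpg, 6
                )
                if n_bins == 1:
                    meth = meth.mean(axis=1, keepdims=True)
                    cpg_b = cpg.sum(axis=1, keepdims=True)
                else:
                    cpg_b = cpg
                norm = np.zeros_like(meth, dtype=float)
                nz = cpg_b > 0
                norm[nz] = meth[nz] / cpg_b[nz]
                blocks.append(meth)
                meta.append(MarkMeta(mspec.name, mspec.mark_type, "absolute"))
                blocks.append(norm)
                meta.append(MarkMeta(mspec.name, mspec.mark_type, "cpg_normalized"))
            else:
                blocks.append(raw)
                meta.append(MarkMeta(mspec.name, mspec.mark_type))
        return assemble_matrix(
            blocks, meta, genes, n_bins=n_bins, q=q, cell_line=cell_line,
            gene_type=gene_type, region_type="tss_flank",
        )

    def gex_raw(self, cell_line: str, gene_type: str = "protein_coding") -> np.ndarray:
        rows = self.analysis_genes(gene_type)
        return self.gex[cell_line][rows]

    # ------------------------------------------------------------------
    # file emission

    def write(self, outdir, emit_fasta: bool = False) -> dict:
        """Write GTF, per-mark tracks, CAGE, CpG/blacklist BEDs; return paths."""
        cfg = self.config
        os.makedirs(outdir, exist_ok=True)
        paths: dict = {"outdir": str(outdir)}
        gtf = os.path.join(outdir, "genes.gtf")
        self._write_gtf(gtf)
        paths["gtf"] = gtf
        sizes = os.path.join(outdir, "chrom.sizes")
        with open(sizes, "w") as fh:
            for chrom in sorted(self.chrom_sizes):
                fh.write(f"{chrom}\t{self.chrom_sizes[chrom]}\n")
        paths["chrom_sizes"] = sizes
        bl = os.path.join(outdir, "blacklist.bed")
        with open(bl, "w") as fh:
            for chrom, s, e in sorted(self.blacklist):
                fh.write(f"{chrom}\t{s}\t{e}\n")
        paths["blacklist"] = bl
        paths["tracks"] = {}
        for c in cfg.cell_lines:
            cdir = os.path.join(outdir, "tracks", c)
            os.makedirs(cdir, exist_ok=True)
            paths["tracks"][c] = {}
            for mspec in cfg.marks:
                p = os.path.join(cdir, f"{mspec.name}.bedGraph")
                if mspec.is_methylation:
                    self._write_meth_track(c, p)
                else:
                    self._write_mark_track(c, mspec.name, p)
                paths["tracks"][c][mspec.name] = p
        paths["cage"] = {}
        for c in cfg.cell_lines:
            cdir = os.path.join(outdir, "cage")
            os.makedirs(cdir, exist_ok=True)
            pp = os.path.join(cdir, f"{c}.plus.bedGraph")
            pm = os.path.join(cdir, f"{c}.minus.bedGraph")
            self._write_cage(c, pp, pm)
            paths["cage"][c] = {"plus": pp, "minus": pm}
        if cfg.include_methylation:
            cpg = os.path.join(outdir, "cpg.bed")
            with open(cpg, "w") as fh:
                for chrom in sorted(self.cpg_positions):
                    for p in self.cpg_positions[chrom]:
                        fh.write(f"{chrom}\t{p}\t{p + 2}\n")
            paths["cpg_bed"] = cpg
            if emit_fasta:
                fa = os.path.join(outdir, "genome.fa")
                self._write_fasta(fa)
                paths["fasta"] = fa
        tj = os.path.join(outdir, "truth.json")
        with open(tj, "w") as fh:
            t = asdict(self.truth)
            t["config"]["marks"] = [asdict(m) for m in cfg.marks]
            t["config"]["expression"] = asdict(cfg.expression)
            json.dump(t, fh, indent=1, sort_keys=True, default=str)
        paths["truth"] = tj
        return paths

    def _write_gtf(self, path):
        with open(path, "w") as fh:
            fh.write("##description: synthetic annotation\n")
            for g in self.genes:
                attrs = (
                    f'gene_id "{g["gene_id"]}"; '
                    f'gene_type "{g["gene_type"]}";'
                )
                fh.write(
                    f'{g["chrom"]}\tsynthetic\tgene\t{g["start"] + 1}\t'
                    f'{g["end"]}\t.\t{g["strand"]}\t.\t{attrs}\n'
                )
                for t, (ts, te) in enumerate(g["transcripts"], start=1):
                    ta = attrs + f' transcript_id "{g["gene_id"]}.{t}";'
                    fh.write(
                        f'{g["chrom"]}\tsynthetic\ttranscript\t{ts + 1}\t'
                        f'{te}\t.\t{g["strand"]}\t.\t{ta}\n'
                    )

    def _iter_flank_bins(self):
        for i, g in enumerate(self.genes):
            lo = g["tss"] - self.config.flank
            yield i, g, lo

    def _write_mark_track(self, cell, mark, path):
        bv = self.bin_values[cell][mark]
        with open(path, "w") as fh:
            for i, g, lo in self._iter_flank_bins():
                for b in range(_N_BINS):
                    v = bv[i, b]
                    if v == 0:
                        continue
                    fh.write(f'{g["chrom"]}\t{lo + b * 100}\t{lo + (b + 1) * 100}\t{v:.10g}\n')

    def _write_meth_track(self, cell, path):
        frac = self.meth_fraction[cell]
        with open(path, "w") as fh:
            for i, g, lo in self._iter_flank_bins():
                for b in range(_N_BINS):
                    v = np.round(frac[i] * self.cpg_bin_counts[i, b], 6)
                    if v == 0:
                        continue
                    fh.write(f'{g["chrom"]}\t{lo + b * 100}\t{lo + (b + 1) * 100}\t{v:.10g}\n')

    def _write_cage(self, cell, path_plus, path_minus):
        gex = self.gex[cell]
        fplus = self.cage_plus_fraction[cell]
        with open(path_plus, "w") as fp, open(path_minus, "w") as fm:
            for i, g, lo in self._iter_flank_bins():
                if gex[i] == 0:
                    continue
                for b in (19, 20):
                    s, e = lo + b * 100, lo + (b + 1) * 100
                    vp = np.round(gex[i] * fplus[i] / 2.0, 6)
                    vm = np.round(gex[i] * (1 - fplus[i]) / 2.0, 6)
                    if vp > 0:
                        fp.write(f'{g["chrom"]}\t{s}\t{e}\t{vp:.10g}\n')
                    if vm > 0:
                        fm.write(f'{g["chrom"]}\t{s}\t{e}\t{-vm:.10g}\n')

    def _write_fasta(self, path):
        # background alphabet {A, T, G} so the only CG dimers are planted CpGs
        rng = np.random.default_rng(self.config.seed + 1)
        with open(path, "w") as fh:
            for chrom in sorted(self.chrom_sizes):
                size = self.chrom_sizes[chrom]
                seq = rng.choice(np.array(list("ATG")), size=size)
                for p in self.cpg_positions.get(chrom, []):
                    if p + 1 < size:
                        seq[p] = "C"
                        seq[p + 1] = "G"
                fh.write(f">{chrom}\n")
                s = "".join(seq)
                for k in range(0, size, 80):
                    fh.write(s[k:k + 80] + "\n")


def generate_world(config: WorldConfig, outdir, emit_fasta: bool = False):
    """Generate a world and write its files; returns (paths, world)."""
    world = SyntheticWorld(config)
    paths = world.write(outdir, emit_fasta=emit_fasta)
    return paths, world


def world_report(world: SyntheticWorld) -> str:
    """Human-readable summary of a world's planted structure."""
    t = world.truth
    cfg = world.config
    lines = [
        f"Synthetic world: {cfg.n_genes} genes, {len(cfg.marks)} marks, "
        f"{cfg.n_cell_lines} cell line(s), seed={cfg.seed}",
        f"latent dims: shared={cfg.latent_dim} specific={cfg.latent_dim_specific}; "
        f"target r = {cfg.target_r}; profile = {cfg.signal_profile}",
        f"blacklisted genes: {t.n_blacklisted}; chrX genes: {t.n_sex_chrom}",
        f"expected first selection (max information): {t.expected_first_selection}",
        "",
        "mark            rule           noise_sd  theoretical_r  min_xcell_cos",
    ]
    for m in cfg.marks:
        lines.append(
            f"{m.name:<15} {m.rule_class:<14} "
            f"{t.mark_noise_sd[m.name]:>8.3f}  "
            f"{t.theoretical_r[m.name]:>13.3f}  "
            f"{t.loading_similarity[m.name]:>13.3f}"
        )
    return "\n".join(lines)
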