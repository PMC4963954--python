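"""Seeded multi-assay, multi-cell-type simulator with planted ground truth.

The generator emulates the data structure of a two-cell-type epigenome
study: ChIP-seq peak sets and binned coverage tracks for H3K4me1, H3K27ac,
H3K4me3 and H3K27me3 in a germline stem cell population ("fgsc") and an
embryonic stem cell population ("esc"); an affinity-capture DNA methylation
track plus matched input for fgsc; per-CpG bisulfite counts for a male
germline population ("mgsc"); and an expression table coupled to promoter
methylation and enhancer class.

The genome is a single synthetic chromosome divided into equal gene slots.
Each slot holds one gene (body + strand-aware promoter); distal zones of
selected slots hold one enhancer, one transposable-element locus, one
imprinted-DMR-like locus, or one promoter-free H3K4me3 peak, so that planted
features never collide and enhancers are always > 2 kb from every TSS.

Planted truth (enhancer classes, bivalent promoters, per-cell promoter/body
methylation, sex-specific methylation, TE methylation, knockdown-responsive
genes) is returned as a :class:`GroundTruth` and serialisable to JSON, so
every downstream module can be scored against it.

Read noise is negative-binomial with configurable dispersion; bisulfite
counts are beta-binomial around the configured methylated/unmethylated
means.  All randomness flows from per-assay child streams of the single
config seed, so outputs are byte-identical across runs and platforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    TSSIndex,
    write_bed,
    write_gene_models,
)
from .methylation import BisulfiteTable, CpGIndex, MethylWindow
from .stats import ExpressionTable
from .tracks import RPKM, BinnedTrack, track_from_counts, write_bedgraph

TE_FAMILIES = ("LINE_L1", "LTR_ERV1", "IAP", "DNA", "SINE_B1", "SINE_B2")
ENHANCER_CLASSES = ("shared", "fgsc_specific", "esc_specific", "weak")
CELL_TYPES = ("fgsc", "esc")

# named RNG sub-streams: every assay draws from default_rng([seed, stream])
_STREAMS = {
    "genome": 0,
    ("H3K4me1", "fgsc"): 11,
    ("H3K27ac", "fgsc"): 12,
    ("H3K4me3", "fgsc"): 13,
    ("H3K27me3", "fgsc"): 14,
    ("H3K4me1", "esc"): 21,
    ("H3K27ac", "esc"): 22,
    ("H3K4me3", "esc"): 23,
    ("H3K27me3", "esc"): 24,
    "capture": 30,
    "input": 31,
    "bisulfite": 32,
    "expression": 40,
    "correlation": 50,
}


class SizingError(ValueError):
    """The requested features do not fit the requested genome."""


@dataclass
class SimulationConfig:
    """All tunable knobs of the simulator; defaults define the reference
    study conditions used by the recovery tests."""

    seed: int = 0
    chrom: str = "chrS"
    genome_length: int = 10_000_000
    n_genes: int = 500
    bin_width: int = 50
    n_enhancers_per_class: int = 100
    peak_width_mean: int = 1000
    signal_depth: int = 1_000_000
    noise_dispersion: float = 0.1
    # beta-binomial means at methylated / unmethylated CpGs
    methyl_beta_params: tuple[float, float] = (0.8, 0.05)
    beta_concentration: float = 50.0
    fraction_promoter_methylated: float = 0.3
    # of the methylated promoters, this fraction is methylated in both sexes
    fraction_shared_methylation: float = 0.6
    bisulfite_depth_mean: float = 30.0
    fraction_promoter_cpg_island: float = 0.7
    fraction_body_given_promoter: float = 0.92
    n_body_only_genes: int = 50
    # promoter chromatin composition per cell type
    n_bivalent: dict = field(default_factory=lambda: {"fgsc": 40, "esc": 120})
    n_repressed: dict = field(default_factory=lambda: {"fgsc": 60, "esc": 40})
    n_silent: dict = field(default_factory=lambda: {"fgsc": 50, "esc": 40})
    k4me3_distal_fraction: float = 0.1
    # expected reads per bin
    peak_height: float = 20.0
    weak_peak_height: float = 8.0
    k27me3_peak_height: float = 10.0
    background_fraction: float = 0.2
    n_te_per_family: int = 30
    te_width: int = 500
    n_dmrs: int = 6
    # TE methylation frequency per family: (fgsc, mgsc)
    te_methyl_freq: dict = field(default_factory=lambda: {
        "LINE_L1": (0.3, 0.75), "LTR_ERV1": (0.3, 0.75), "IAP": (0.35, 0.8),
        "DNA": (0.75, 0.3), "SINE_B1": (0.75, 0.3), "SINE_B2": (0.7, 0.35),
    })
    cpg_background_spacing: int = 150
    cpg_island_spacing: int = 10
    # expression
    methylation_expression_ratio: float = 4.0
    enhancer_expression_fold: float = 4.0
    n_knockdown_responsive: int = 150
    knockdown_fold_range: tuple[float, float] = (2.0, 6.0)
    expression_depth_per_fpkm: float = 50.0

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("genome_length", "bin_width", "peak_width_mean",
                     "signal_depth", "te_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_enhancers_per_class", "n_te_per_family",
                     "n_dmrs", "n_body_only_genes", "n_knockdown_responsive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        for name in ("fraction_promoter_methylated", "fraction_shared_methylation",
                     "fraction_promoter_cpg_island", "fraction_body_given_promoter",
                     "k4me3_distal_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def slot_width(self) -> int:
        if self.n_genes == 0:
            return self.genome_length
        return self.genome_length // self.n_genes

    def rng(self, stream) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methyl_beta_params"] = list(self.methyl_beta_params)
        d["knockdown_fold_range"] = list(self.knockdown_fold_range)
        d["te_methyl_freq"] = {k: list(v) for k, v in self.te_methyl_freq.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "methyl_beta_params" in d:
            d["methyl_beta_params"] = tuple(d["methyl_beta_params"])
        if "knockdown_fold_range" in d:
            d["knockdown_fold_range"] = tuple(d["knockdown_fold_range"])
        if "te_methyl_freq" in d:
            d["te_methyl_freq"] = {k: tuple(v)
                                   for k, v in d["te_methyl_freq"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage, serialisable to JSON."""

    enhancer_classes: dict  # enhancer id -> class name
    bivalent_genes: dict  # cell type -> set of gene ids
    promoter_chromatin: dict  # cell type -> {gene id -> active|bivalent|repressed|silent}
    promoter_methyl: dict  # cell type (fgsc/mgsc) -> set of methylated gene ids
    body_methyl: dict  # cell type -> set of gene ids
    sex_specific_methyl: dict  # female_only|male_only|both|neither -> set of gene ids
    te_methyl: dict  # cell type -> set of TE locus ids
    dmr_states: dict  # dmr id -> female_only|male_only
    knockdown_genes: set

    def to_json(self, path) -> None:
        def enc(v):
            if isinstance(v, set):
                return sorted(v)
            if isinstance(v, dict):
                return {k: enc(x) for k, x in sorted(v.items())}
            return v

        with open(path, "w") as fh:
            json.dump({k: enc(v) for k, v in dataclasses.asdict(self).items()},
                      fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        for cell_key in ("bivalent_genes", "promoter_methyl", "body_methyl",
                         "te_methyl", "sex_specific_methyl"):
            d[cell_key] = {k: set(v) for k, v in d[cell_key].items()}
        d["knockdown_genes"] = set(d["knockdown_genes"])
        return cls(**d)


@dataclass
class SyntheticGenome:
    chrom_lengths: dict
    genes: list[GeneModel]
    cpgs: CpGIndex
    cpg_islands: PeakSet
    transposons: PeakSet
    dmrs: PeakSet
    enhancers: PeakSet  # all planted enhancer loci, named enh_XXXX

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


def _island_interval(gene: GeneModel, half: int = 500) -> GenomicInterval:
    return GenomicInterval(gene.chrom, gene.tss - half, gene.tss + half,
                           name=f"island_{gene.gene_id}")


# ---------------------------------------------------------------------------
# Genome + truth
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> tuple[SyntheticGenome, GroundTruth]:
    """Lay out genes, CpGs, enhancer loci, TEs and DMR loci, and draw the
    planted ground truth for every assay.  Deterministic under the seed."""
    cfg = config
    chrom = cfg.chrom
    lengths = {chrom: cfg.genome_length}
    rng = cfg.rng("genome")

    n_enh_total = 4 * cfg.n_enhancers_per_class
    n_te_total = cfg.n_te_per_family * len(TE_FAMILIES)
    if cfg.n_genes > 0:
        slot = cfg.slot_width
        if slot < 18_000:
            raise SizingError(
                f"gene slots of {slot} bp are too small; need >= 18000 "
                "(increase genome_length or decrease n_genes)"
            )
        if n_enh_total > cfg.n_genes:
            raise SizingError("more enhancers requested than gene slots")
        if n_te_total + cfg.n_dmrs > cfg.n_genes:
            raise SizingError("TE loci + DMRs exceed the number of gene slots")
        for name in ("n_bivalent", "n_repressed", "n_silent"):
            for cell, n in getattr(cfg, name).items():
                if n > cfg.n_genes:
                    raise SizingError(f"{name}[{cell}] exceeds n_genes")
    elif n_enh_total or n_te_total or cfg.n_dmrs:
        raise SizingError("cannot place features on a genome with no gene slots")

    genes: list[GeneModel] = []
    enhancer_ivs: list[GenomicInterval] = []
    te_ivs: list[GenomicInterval] = []
    dmr_ivs: list[GenomicInterval] = []
    distal_k4me3_zones: list[GenomicInterval] = []

    if cfg.n_genes > 0:
        slot = cfg.slot_width
        body_len_max = min(8000, slot - 11_502)
        strands = rng.choice(["+", "-"], size=cfg.n_genes)
        body_lens = rng.integers(4000, body_len_max + 1, size=cfg.n_genes)
        enh_slots = rng.permutation(cfg.n_genes)[:n_enh_total]
        enh_widths = np.clip(
            np.rint(rng.normal(cfg.peak_width_mean, cfg.peak_width_mean * 0.1,
                               size=n_enh_total)),
            200, 1500,
        ).astype(int)
        for i in range(cfg.n_genes):
            s0 = i * slot
            body_start = s0 + 2500
            body_end = body_start + int(body_lens[i])
            strand = str(strands[i])
            tss = body_start if strand == "+" else body_end - 1
            genes.append(GeneModel(f"gene_{i:04d}", chrom, strand, tss,
                                   body_start, body_end))
            distal_k4me3_zones.append(
                GenomicInterval(chrom, s0 + slot - 2800, s0 + slot - 2000)
            )
        for j, si in enumerate(enh_slots):
            center = int(si) * slot + slot - 5500
            w = int(enh_widths[j])
            enhancer_ivs.append(
                GenomicInterval(chrom, center - w // 2, center - w // 2 + w,
                                name=f"enh_{j:04d}")
            )
        for t in range(n_te_total):
            family = TE_FAMILIES[t % len(TE_FAMILIES)]
            s0 = t * slot
            te_ivs.append(
                GenomicInterval(chrom, s0 + slot - 3600,
                                s0 + slot - 3600 + cfg.te_width,
                                name=f"{family}", score=float(t))
            )
        for d in range(cfg.n_dmrs):
            s0 = (cfg.n_genes - 1 - d) * slot
            dmr_ivs.append(
                GenomicInterval(chrom, s0 + slot - 4700, s0 + slot - 3700,
                                name=f"dmr_{d}")
            )

    # --- truth: enhancer classes (interleaved so class is position-free)
    enhancer_classes = {
        iv.name: ENHANCER_CLASSES[j % len(ENHANCER_CLASSES)]
        for j, iv in enumerate(enhancer_ivs)
    }

    # --- truth: promoter chromatin per cell type
    gene_ids = [g.gene_id for g in genes]
    promoter_chromatin: dict[str, dict[str, str]] = {}
    bivalent_genes: dict[str, set] = {}
    for cell in CELL_TYPES:
        n_biv = cfg.n_bivalent.get(cell, 0)
        n_rep = cfg.n_repressed.get(cell, 0)
        n_sil = cfg.n_silent.get(cell, 0)
        if n_biv + n_rep + n_sil > len(gene_ids):
            raise SizingError(f"promoter chromatin classes exceed n_genes ({cell})")
        perm = rng.permutation(len(gene_ids))
        state = {}
        for rank, gi in enumerate(perm):
            gid = gene_ids[gi]
            if rank < n_biv:
                state[gid] = "bivalent"
            elif rank < n_biv + n_rep:
                state[gid] = "repressed"
            elif rank < n_biv + n_rep + n_sil:
                state[gid] = "silent"
            else:
                state[gid] = "active"
        promoter_chromatin[cell] = state
        bivalent_genes[cell] = {g for g, s in state.items() if s == "bivalent"}

    # --- truth: CpG islands and promoter methylation (sex-partitioned)
    n_island = int(round(cfg.fraction_promoter_cpg_island * len(gene_ids)))
    island_gene_idx = rng.permutation(len(gene_ids))[:n_island]
    island_genes = [gene_ids[i] for i in sorted(island_gene_idx)]
    n_meth = int(round(cfg.fraction_promoter_methylated * len(gene_ids)))
    n_both = int(round(cfg.fraction_shared_methylation * n_meth))
    n_female = n_meth - n_both
    n_male = n_meth - n_both
    if n_both + n_female + n_male > len(island_genes):
        raise SizingError(
            "methylated promoters exceed CpG-island promoters; raise "
            "fraction_promoter_cpg_island or lower fraction_promoter_methylated"
        )
    picked = rng.permutation(len(island_genes))
    both = {island_genes[i] for i in picked[:n_both]}
    female_only = {island_genes[i] for i in picked[n_both:n_both + n_female]}
    male_only = {island_genes[i] for i in picked[n_both + n_female:
                                                 n_both + n_female + n_male]}
    neither = set(gene_ids) - both - female_only - male_only
    promoter_methyl = {
        "fgsc": female_only | both,
        "mgsc": male_only | both,
    }
    sex_specific = {
        "female_only": female_only,
        "male_only": male_only,
        "both": both,
        "neither": neither,
    }

    # --- truth: gene-body methylation per cell
    body_methyl: dict[str, set] = {}
    for cell in ("fgsc", "mgsc"):
        meth = sorted(promoter_methyl[cell])
        keep = rng.random(len(meth)) < cfg.fraction_body_given_promoter
        body = {g for g, k in zip(meth, keep) if k}
        pool = sorted(set(gene_ids) - promoter_methyl[cell])
        n_only = min(cfg.n_body_only_genes, len(pool))
        extra = rng.permutation(len(pool))[:n_only]
        body |= {pool[i] for i in extra}
        body_methyl[cell] = body

    # --- truth: TE methylation per cell, by family frequency
    te_methyl: dict[str, set] = {"fgsc": set(), "mgsc": set()}
    te_named = []
    for t, iv in enumerate(te_ivs):
        locus_id = f"{iv.name}_{t:03d}"
        te_named.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                        name=iv.name, score=float(t)))
        f_f, f_m = cfg.te_methyl_freq.get(iv.name, (0.5, 0.5))
        if rng.random() < f_f:
            te_methyl["fgsc"].add(locus_id)
        if rng.random() < f_m:
            te_methyl["mgsc"].add(locus_id)

    # --- truth: DMR states alternate female/male
    dmr_states = {
        iv.name: ("female_only" if d % 2 == 0 else "male_only")
        for d, iv in enumerate(dmr_ivs)
    }

    # --- truth: knockdown-responsive genes
    kd_idx = rng.permutation(len(gene_ids))[:min(cfg.n_knockdown_responsive,
                                                 len(gene_ids))]
    knockdown_genes = {gene_ids[i] for i in kd_idx}

    # --- CpG positions: sparse background grid + dense islands
    positions = [np.arange(50, cfg.genome_length, cfg.cpg_background_spacing,
                           dtype=np.int64)]
    island_ivs = []
    gene_by_id = {g.gene_id: g for g in genes}
    for gid in island_genes:
        island_ivs.append(_island_interval(gene_by_id[gid]))
    # every other locus of each TE family carries an overlapping CpG island
    for t, iv in enumerate(te_named):
        if (t // len(TE_FAMILIES)) % 2 == 0:
            island_ivs.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                              name=f"island_te_{t:03d}"))
    dense_sources = island_ivs + dmr_ivs
    for iv in dense_sources:
        positions.append(np.arange(iv.start, iv.end, cfg.cpg_island_spacing,
                                   dtype=np.int64))
    all_pos = np.unique(np.concatenate(positions)) if positions else \
        np.empty(0, dtype=np.int64)
    all_pos = all_pos[all_pos < cfg.genome_length]

    genome = SyntheticGenome(
        chrom_lengths=lengths,
        genes=genes,
        cpgs=CpGIndex({chrom: all_pos}),
        cpg_islands=PeakSet("CpG_island", "", island_ivs),
        transposons=PeakSet("TE", "", te_named),
        dmrs=PeakSet("DMR", "", dmr_ivs),
        enhancers=PeakSet("enhancer_locus", "", enhancer_ivs),
    )
    truth = GroundTruth(
        enhancer_classes=enhancer_classes,
        bivalent_genes=bivalent_genes,
        promoter_chromatin=promoter_chromatin,
        promoter_methyl=promoter_methyl,
        body_methyl=body_methyl,
        sex_specific_methyl=sex_specific,
        te_methyl=te_methyl,
        dmr_states=dmr_states,
        knockdown_genes=knockdown_genes,
    )
    # stash the distal H3K4me3 zones for the ChIP generator
    genome._distal_k4me3_zones = distal_k4me3_zones  # type: ignore[attr-defined]
    return genome, truth


# ---------------------------------------------------------------------------
# Read-count noise
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = m + d m^2 (Poisson as d -> 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-9:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _add_peak(expected: np.ndarray, iv: GenomicInterval, height: float,
              bin_width: int) -> None:
    """Add `height` expected reads per bin over the peak, prorating edges."""
    b0 = iv.start // bin_width
    b1 = (iv.end - 1) // bin_width
    for b in range(b0, min(b1, len(expected) - 1) + 1):
        lo = max(iv.start, b * bin_width)
        hi = min(iv.end, (b + 1) * bin_width)
        expected[b] += height * (hi - lo) / bin_width


# ---------------------------------------------------------------------------
# ChIP assays
# ---------------------------------------------------------------------------

def _enhancer_peak_spec(cfg: SimulationConfig, truth: GroundTruth,
                        genome: SyntheticGenome, mark: str,
                        cell_type: str) -> list[tuple[GenomicInterval, float]]:
    """(interval, expected height) for enhancer-mark peaks in one cell."""
    specific = f"{cell_type}_specific"
    out = []
    for iv in genome.enhancers:
        klass = truth.enhancer_classes[iv.name]
        if mark == "H3K4me1":
            if klass in ("shared", specific):
                out.append((iv, cfg.peak_height))
            elif klass == "weak":
                out.append((iv, cfg.weak_peak_height))
        elif mark == "H3K27ac":
            if klass in ("shared", specific):
                out.append((iv, cfg.peak_height))
    return out


def generate_chip_assay(
    config: SimulationConfig,
    genome: SyntheticGenome,
    truth: GroundTruth,
    mark: str,
    cell_type: str,
) -> tuple[PeakSet, BinnedTrack]:
    """Peak set and RPKM track for one histone mark in one cell type.

    Peaks are placed per the planted truth (enhancer classes for
    H3K4me1/H3K27ac; promoter chromatin states for H3K4me3/H3K27me3, plus a
    configurable fraction of promoter-free H3K4me3 peaks).  The track draws
    negative-binomial counts per bin with elevated mean inside peaks, so
    track and peak set are mutually consistent.
    """
    cfg = config
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if mark not in ("H3K4me1", "H3K27ac", "H3K4me3", "H3K27me3"):
        raise ValueError(f"unknown mark {mark!r}")
    chrom = cfg.chrom
    rng = cfg.rng((mark, cell_type))
    peaks: list[tuple[GenomicInterval, float]] = []
    if mark in ("H3K4me1", "H3K27ac"):
        peaks = _enhancer_peak_spec(cfg, truth, genome, mark, cell_type)
    elif mark == "H3K4me3":
        state = truth.promoter_chromatin[cell_type]
        prom = []
        for g in genome.genes:
            if state[g.gene_id] in ("active", "bivalent"):
                prom.append((GenomicInterval(chrom, g.tss - 800, g.tss + 800,
                                             name=f"k4me3_{g.gene_id}"),
                             cfg.peak_height))
        f = cfg.k4me3_distal_fraction
        n_distal = int(round(len(prom) * f / (1 - f))) if f < 1 else 0
        zones = getattr(genome, "_distal_k4me3_zones", [])
        zone_idx = rng.permutation(len(zones))[:n_distal] if zones else []
        distal = [
            (GenomicInterval(chrom, zones[i].start, zones[i].end,
                             name=f"k4me3_distal_{j:03d}"), cfg.peak_height)
            for j, i in enumerate(sorted(zone_idx))
        ]
        peaks = prom + distal
    elif mark == "H3K27me3":
        state = truth.promoter_chromatin[cell_type]
        for g in genome.genes:
            if state[g.gene_id] in ("repressed", "bivalent"):
                peaks.append(
                    (GenomicInterval(chrom, g.tss - 1500, g.tss + 1500,
                                     name=f"k27me3_{g.gene_id}"),
                     cfg.k27me3_peak_height)
                )
    else:
        raise ValueError(f"unknown mark {mark!r}")

    nbins = -(-cfg.genome_length // cfg.bin_width)
    expected = np.full(nbins, cfg.background_fraction * cfg.signal_depth / nbins)
    for iv, h in peaks:
        _add_peak(expected, iv, h, cfg.bin_width)
    counts = _nb_sample(rng, expected, cfg.noise_dispersion).astype(float)
    track = track_from_counts({chrom: counts}, genome.chrom_lengths,
                              cfg.bin_width, mode=RPKM)
    peak_set = PeakSet(mark, cell_type, [iv for iv, _ in peaks])
    return peak_set, track


# ---------------------------------------------------------------------------
# Methylation assays
# ---------------------------------------------------------------------------

def _methylated_regions(cfg: SimulationConfig, genome: SyntheticGenome,
                        truth: GroundTruth, cell: str) -> list[GenomicInterval]:
    """All intervals planted as methylated in `cell` (fgsc or mgsc)."""
    gene_by_id = {g.gene_id: g for g in genome.genes}
    regions = []
    for gid in sorted(truth.promoter_methyl[cell]):
        regions.append(_island_interval(gene_by_id[gid]))
    for gid in sorted(truth.body_methyl[cell]):
        iv = gene_by_id[gid].body_interior()
        if iv is not None:
            regions.append(iv)
    for t, iv in enumerate(genome.transposons):
        if f"{iv.name}_{t:03d}" in truth.te_methyl[cell]:
            regions.append(iv)
    label = "female_only" if cell == "fgsc" else "male_only"
    for iv in genome.dmrs:
        if truth.dmr_states.get(iv.name) == label:
            regions.append(iv)
    return regions


def cpg_methylation_states(cfg: SimulationConfig, genome: SyntheticGenome,
                           truth: GroundTruth, cell: str) -> np.ndarray:
    """Boolean methylation state per CpG (sorted order of the CpG index)."""
    pos = genome.cpgs.pos[cfg.chrom]
    state = np.zeros(len(pos), dtype=bool)
    for iv in _methylated_regions(cfg, genome, truth, cell):
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        state[lo:hi] = True
    return state


@dataclass
class MethylationAssays:
    capture_fgsc: BinnedTrack
    input_fgsc: BinnedTrack
    bisulfite_mgsc: BisulfiteTable


def generate_methylation_assays(
    config: SimulationConfig,
    genome: SyntheticGenome,
    truth: GroundTruth,
) -> MethylationAssays:
    """Capture + input tracks for fgsc and per-CpG bisulfite counts for mgsc.

    Capture reads concentrate on methylated CpGs: the non-background depth
    is spread uniformly over methylated CpGs, so a bin's expected count is
    proportional to the methylated-CpG count it contains.  Bisulfite (C, T)
    pairs are beta-binomial with the configured means at methylated and
    unmethylated CpGs.
    """
    cfg = config
    chrom = cfg.chrom
    pos = genome.cpgs.pos[chrom]
    nbins = -(-cfg.genome_length // cfg.bin_width)

    # capture (fgsc)
    state_f = cpg_methylation_states(cfg, genome, truth, "fgsc")
    meth_per_bin = np.bincount(pos[state_f] // cfg.bin_width,
                               minlength=nbins).astype(float)
    n_meth = int(state_f.sum())
    bg = cfg.background_fraction * cfg.signal_depth / nbins
    rate = ((1 - cfg.background_fraction) * cfg.signal_depth / n_meth
            if n_meth else 0.0)
    expected = bg + rate * meth_per_bin
    cap_counts = _nb_sample(cfg.rng("capture"), expected,
                            cfg.noise_dispersion).astype(float)
    capture = track_from_counts({chrom: cap_counts}, genome.chrom_lengths,
                                cfg.bin_width, mode=RPKM)

    # matched input (fgsc): uniform
    in_expected = np.full(nbins, cfg.signal_depth / nbins)
    in_counts = _nb_sample(cfg.rng("input"), in_expected,
                           cfg.noise_dispersion).astype(float)
    input_track = track_from_counts({chrom: in_counts}, genome.chrom_lengths,
                                    cfg.bin_width, mode=RPKM)

    # bisulfite (mgsc)
    state_m = cpg_methylation_states(cfg, genome, truth, "mgsc")
    rng = cfg.rng("bisulfite")
    cov = rng.poisson(cfg.bisulfite_depth_mean, size=len(pos))
    mu_meth, mu_unmeth = cfg.methyl_beta_params
    mu = np.where(state_m, mu_meth, mu_unmeth)
    kappa = cfg.beta_concentration
    p = rng.beta(np.maximum(mu * kappa, 1e-9),
                 np.maximum((1 - mu) * kappa, 1e-9))
    c = rng.binomial(cov, p)
    keep = cov > 0
    table = BisulfiteTable.from_arrays(
        chrom, pos[keep], c[keep], (cov - c)[keep]
    )
    return MethylationAssays(capture, input_track, table)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: SimulationConfig,
    genome: SyntheticGenome,
    truth: GroundTruth,
) -> ExpressionTable:
    """FPKM + counts for conditions fgsc, esc and fgsc_kd (knockdown).

    Genes with a methylated fgsc promoter are expressed lower in fgsc by
    ``methylation_expression_ratio``; genes nearest a cell-type-specific
    active enhancer are boosted in that cell type; knockdown-responsive
    genes gain a fold >= 2 in the knockdown condition.
    """
    cfg = config
    rng = cfg.rng("expression")
    genes = [g.gene_id for g in genome.genes]
    n = len(genes)
    conditions = ["fgsc", "esc", "fgsc_kd"]
    base = rng.lognormal(mean=2.0, sigma=1.0, size=n)
    noise = rng.lognormal(mean=0.0, sigma=0.25, size=(n, 3))
    fpkm = base[:, None] * noise

    meth_f = np.array([g in truth.promoter_methyl["fgsc"] for g in genes])
    fpkm[meth_f, 0] /= cfg.methylation_expression_ratio
    fpkm[meth_f, 2] /= cfg.methylation_expression_ratio

    # enhancer-proximal boost: nearest gene within 200 kb of each specific
    # active enhancer, per cell type
    index = TSSIndex(genome.genes)
    boost = {"fgsc_specific": set(), "esc_specific": set()}
    from .core import nearest_gene_within  # local import to avoid cycle noise

    for iv in genome.enhancers:
        klass = truth.enhancer_classes[iv.name]
        if klass in boost:
            gid = nearest_gene_within(iv, index)
            if gid is not None:
                boost[klass].add(gid)
    col = {"fgsc_specific": 0, "esc_specific": 1}
    for klass, gids in boost.items():
        mask = np.array([g in gids for g in genes])
        fpkm[mask, col[klass]] *= cfg.enhancer_expression_fold
        if klass == "fgsc_specific":
            fpkm[mask, 2] *= cfg.enhancer_expression_fold

    kd = np.array([g in truth.knockdown_genes for g in genes])
    lo, hi = cfg.knockdown_fold_range
    folds = rng.uniform(lo, hi, size=int(kd.sum()))
    fpkm[kd, 2] *= folds

    counts = rng.poisson(fpkm * cfg.expression_depth_per_fpkm)
    return ExpressionTable(genes, conditions, fpkm, counts)


# ---------------------------------------------------------------------------
# Paired scores with a known latent correlation (for correlation-recovery
# checks of the cross-platform comparison)
# ---------------------------------------------------------------------------

def correlated_window_scores(
    n_windows: int, rho: float, seed: int, chrom: str = "chrS",
) -> tuple[list[MethylWindow], list[MethylWindow]]:
    """Paired capture/bisulfite window scores from a Gaussian copula.

    Latent (Z1, Z2) are standard bivariate normal with correlation ``rho``;
    the capture score is an affine map of Z1 onto a positive rms-like scale
    and the bisulfite score is the probit transform of Z2 (a valid ams in
    [0, 1]).  The affine map preserves the Pearson correlation exactly; the
    probit map attenuates it by ~2 %, keeping the observed r close to rho.
    """
    rng = np.random.default_rng([seed, _STREAMS["correlation"]])
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n_windows)
    from scipy.stats import norm

    cap_scores = 10.0 + 3.0 * z[:, 0]
    bis_scores = norm.cdf(z[:, 1])
    cap, bis = [], []
    for i in range(n_windows):
        iv = GenomicInterval(chrom, 1 + i * 1000, 1 + i * 1000 + 500,
                             name=f"w{i}:1")
        cap.append(MethylWindow(iv, "capture", float(cap_scores[i]), 100, 10))
        bis.append(MethylWindow(iv, "bisulfite", float(bis_scores[i]), 100, 10))
    return cap, bis


# ---------------------------------------------------------------------------
# Full simulation + on-disk bundle
# ---------------------------------------------------------------------------

@dataclass
class Simulation:
    config: SimulationConfig
    genome: SyntheticGenome
    truth: GroundTruth
    chip: dict  # (mark, cell) -> (PeakSet, BinnedTrack)
    methylation: MethylationAssays
    expression: ExpressionTable


def simulate(config: SimulationConfig) -> Simulation:
    """Run every generator stage under the config seed."""
    genome, truth = generate_genome(config)
    chip = {}
    for cell in CELL_TYPES:
        for mark in ("H3K4me1", "H3K27ac", "H3K4me3", "H3K27me3"):
            chip[(mark, cell)] = generate_chip_assay(config, genome, truth,
                                                     mark, cell)
    meth = generate_methylation_assays(config, genome, truth)
    expr = generate_expression(config, genome, truth)
    return Simulation(config, genome, truth, chip, meth, expr)


def write_simulation(sim: Simulation, outdir) -> None:
    """Write the full bundle as plain-text files readable by this package."""
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(sim.config.to_dict(), fh, sort_keys=True)
    write_gene_models(sim.genome.genes, out / "genes.tsv")
    write_bed(sim.genome.cpg_islands, out / "cpg_islands.bed")
    write_bed(sim.genome.transposons, out / "transposons.bed")
    write_bed(sim.genome.dmrs, out / "dmrs.bed")
    write_bed(sim.genome.enhancers, out / "enhancer_loci.bed")
    chrom = sim.config.chrom
    cpg_ivs = [GenomicInterval(chrom, int(p), int(p) + 2)
               for p in sim.genome.cpgs.pos[chrom]]
    write_bed(cpg_ivs, out / "cpgs.bed")
    for (mark, cell), (peaks, track) in sim.chip.items():
        write_bed(peaks, out / f"peaks_{mark}_{cell}.bed")
        write_bedgraph(track, out / f"track_{mark}_{cell}.bedgraph")
    write_bedgraph(sim.methylation.capture_fgsc, out / "capture_fgsc.bedgraph")
    write_bedgraph(sim.methylation.input_fgsc, out / "input_fgsc.bedgraph")
    sim.methylation.bisulfite_mgsc.write_tsv(out / "bisulfite_mgsc.tsv")
    sim.expression.write_tsv(out / "expression.tsv")
    sim.truth.to_json(out / "truth.json")
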