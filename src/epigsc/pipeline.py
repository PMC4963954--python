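"""End-to-end orchestration: simulate -> cluster -> chromatin state ->
methylation -> expression integration, with per-stage caching and a
machine-readable JSON summary.

Each stage reads its inputs from the files the previous stages wrote, so
stages can be recomputed independently: a stage is skipped when its input
digest is unchanged and its outputs still exist, and deleting a stage's
outputs triggers exactly that stage's recompute.  The final ``summary.json``
is written with sorted keys and no timestamps, so a rerun under the same
seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment

from . import __version__
from .chromatin import (
    call_bivalent_promoters,
    classify_enhancers,
    enhancer_class_sets,
    peak_promoter_fraction,
    tss_distance_histogram,
)
from .core import (
    GenomicInterval,
    PeakSet,
    read_bed,
    read_gene_models,
    write_bed,
)
from .methylation import (
    BisulfiteTable,
    CpGIndex,
    InsufficientDataError,
    annotation_methylation_frequency,
    call_bisulfite_regions,
    call_capture_hmrs,
    categorize_genes_by_methylation,
    compare_promoter_calls,
    cross_platform_correlation,
    gene_body_calls,
    locus_methylation_status,
    promoter_gene_calls,
    promoter_windows,
    tile_genome,
    write_methyl_windows,
)
from .simulate import CELL_TYPES, SimulationConfig, GroundTruth, simulate, \
    write_simulation
from .stats import ExpressionTable, class_expression_comparison, two_library_de
from .tracks import (
    blur_rectangular,
    extract_signal_matrix,
    kmeans_cluster,
    read_bedgraph,
    sqrt_transform,
)

DEFAULT_CONFIG = {
    "seed": 17,
    "simulation": {},
    "clustering": {"k": 4, "blur_half_width": 1, "flank": 5000},
    "chromatin": {"exclude_promoter_proximal": True, "proximal_dist": 2000},
    "methylation": {
        "alpha": 0.01,
        "min_fold": 2.0,
        "min_coverage": 10,
        "pseudocount": 1.0,
        "tile_width": 1000,
        "body_interior_margin": 1000,
    },
    "expression": {"alpha": 0.05},
}


# ---------------------------------------------------------------------------
# Scoring helpers (prediction vs planted truth)
# ---------------------------------------------------------------------------

def hungarian_agreement(pred: dict[str, int], truth: dict[str, str]) -> float:
    """Best-case label agreement between a predicted clustering and planted
    classes, maximised over class matchings (Hungarian assignment)."""
    ids = sorted(set(pred) & set(truth))
    if not ids:
        raise ValueError("no shared ids between prediction and truth")
    pred_labels = sorted({pred[i] for i in ids})
    true_labels = sorted({truth[i] for i in ids})
    conf = np.zeros((len(pred_labels), len(true_labels)), dtype=int)
    p_idx = {l: i for i, l in enumerate(pred_labels)}
    t_idx = {l: i for i, l in enumerate(true_labels)}
    for i in ids:
        conf[p_idx[pred[i]], t_idx[truth[i]]] += 1
    rows, cols = linear_sum_assignment(conf, maximize=True)
    return float(conf[rows, cols].sum()) / len(ids)


def precision_recall(pred: set, truth: set) -> tuple[float, float]:
    tp = len(pred & truth)
    precision = tp / len(pred) if pred else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

def load_config(config) -> dict:
    """Accept a path to YAML or a dict; fill defaults section-wise."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise TypeError("config must be a mapping or a path to YAML")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


class _Stage:
    """Digest-keyed stage runner: recompute only when inputs changed or
    outputs are missing."""

    def __init__(self, outdir: Path, log):
        self.outdir = outdir
        self.cache_dir = outdir / ".cache"
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.log = log

    def run(self, name: str, digest: str, outputs: Sequence[Path], func):
        marker = self.cache_dir / f"{name}.json"
        fragment_path = self.outdir / name / "fragment.json"
        if marker.exists() and fragment_path.exists():
            stored = json.loads(marker.read_text())
            if stored.get("digest") == digest and all(
                Path(o).exists() for o in outputs
            ):
                self.log(f"stage {name}: cache hit, skipped")
                return json.loads(fragment_path.read_text())
        (self.outdir / name).mkdir(parents=True, exist_ok=True)
        self.log(f"stage {name}: computing")
        fragment = func()
        fragment_path.write_text(
            json.dumps(fragment, sort_keys=True, indent=1) + "\n"
        )
        marker.write_text(json.dumps({"digest": digest}) + "\n")
        return fragment


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _marks_tracks(simdir: Path, marks_cells):
    out = {}
    for mark, cell in marks_cells:
        out[(mark, cell)] = read_bedgraph(simdir / f"track_{mark}_{cell}.bedgraph")
    return out


def _union_enhancer_candidates(simdir: Path) -> PeakSet:
    """Union of H3K4me1 peaks across cell types, deduplicated by region id."""
    seen = {}
    for cell in CELL_TYPES:
        for iv in read_bed(simdir / f"peaks_H3K4me1_{cell}.bed",
                           "H3K4me1", cell):
            seen.setdefault(iv.id, iv)
    return PeakSet("H3K4me1", "union", list(seen.values()))


def _stage_simulate(cfg: dict, outdir: Path) -> dict:
    sim_cfg = SimulationConfig.from_dict(
        {"seed": cfg["seed"], **cfg["simulation"]}
    )
    sim = simulate(sim_cfg)
    write_simulation(sim, outdir / "simulate")
    truth = sim.truth
    return {
        "n_genes": len(sim.genome.genes),
        "n_enhancers": len(sim.genome.enhancers),
        "n_te_loci": len(sim.genome.transposons),
        "n_dmrs": len(sim.genome.dmrs),
        "n_cpgs": int(sum(len(v) for v in sim.genome.cpgs.pos.values())),
        "planted_bivalent": {c: len(v) for c, v in
                             sorted(truth.bivalent_genes.items())},
        "planted_promoter_methylated": {
            c: len(v) for c, v in sorted(truth.promoter_methyl.items())},
    }


def _stage_cluster(cfg: dict, outdir: Path) -> dict:
    simdir = outdir / "simulate"
    ccfg = cfg["clustering"]
    regions = _union_enhancer_candidates(simdir)
    marks_cells = [("H3K4me1", c) for c in CELL_TYPES] + \
        [("H3K27ac", c) for c in CELL_TYPES]
    tracks = _marks_tracks(simdir, marks_cells)
    matrices = []
    for key in marks_cells:
        track = sqrt_transform(
            blur_rectangular(tracks[key], ccfg["blur_half_width"])
        )
        matrices.append(extract_signal_matrix(track, regions, ccfg["flank"]))
    result = kmeans_cluster(matrices, k=ccfg["k"], seed=cfg["seed"])
    stage_dir = outdir / "cluster"
    by_id = {iv.id: iv for iv in regions}
    with open(stage_dir / "assignments.tsv", "w") as fh:
        fh.write("region_id\tchrom\tstart\tend\tclass\n")
        for rid, lab in zip(result.row_ids, result.labels):
            iv = by_id[rid]
            fh.write(f"{rid}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{lab}\n")
    np.savetxt(stage_dir / "centroids.tsv", result.centroids,
               delimiter="\t", fmt="%.6g")
    truth = GroundTruth.from_json(simdir / "truth.json")
    agreement = hungarian_agreement(result.assignments, truth.enhancer_classes)
    sizes = {str(lab): int((result.labels == lab).sum())
             for lab in range(1, result.k + 1)}
    return {
        "k": result.k,
        "n_regions": len(result.row_ids),
        "class_sizes": sizes,
        "inertia": result.inertia,
        "n_iter": result.n_iter,
        "planted_class_agreement": agreement,
    }


def _read_assignments(outdir: Path) -> dict[str, int]:
    df = pd.read_csv(outdir / "cluster" / "assignments.tsv", sep="\t")
    return dict(zip(df["region_id"], df["class"].astype(int)))


def _stage_chromatin(cfg: dict, outdir: Path) -> dict:
    simdir = outdir / "simulate"
    ccfg = cfg["chromatin"]
    genes = read_gene_models(simdir / "genes.tsv")
    truth = GroundTruth.from_json(simdir / "truth.json")
    stage_dir = outdir / "chromatin"
    fragment: dict = {}

    # enhancer calls per cell type, scored against the planted marks
    for cell in CELL_TYPES:
        k4me1 = read_bed(simdir / f"peaks_H3K4me1_{cell}.bed", "H3K4me1", cell)
        k27ac = read_bed(simdir / f"peaks_H3K27ac_{cell}.bed", "H3K27ac", cell)
        calls = classify_enhancers(
            k4me1, k27ac, genes,
            exclude_promoter_proximal=ccfg["exclude_promoter_proximal"],
            proximal_dist=ccfg["proximal_dist"],
        )
        write_bed(
            [dataclasses.replace(c.interval, name=f"{c.interval.id}|{c.state}")
             for c in calls],
            stage_dir / f"enhancers_{cell}.bed",
        )
        n_active = sum(c.state == "active" for c in calls)
        correct = 0
        for c in calls:
            klass = truth.enhancer_classes.get(c.interval.id)
            expected = "active" if klass in ("shared", f"{cell}_specific") \
                else "poised"
            correct += c.state == expected
        fragment[f"enhancers_{cell}"] = {
            "n_calls": len(calls),
            "n_active": n_active,
            "n_poised": len(calls) - n_active,
            "state_accuracy": correct / len(calls) if calls else float("nan"),
        }
        hist = tss_distance_histogram(
            calls, breaks=list(range(-100_000, 100_001, 10_000))
        )
        fragment[f"enhancers_{cell}"]["tss_distance_histogram"] = \
            [int(x) for x in hist]

    # bivalent promoters per cell type
    for cell in CELL_TYPES:
        k4me3 = read_bed(simdir / f"peaks_H3K4me3_{cell}.bed", "H3K4me3", cell)
        k27me3 = read_bed(simdir / f"peaks_H3K27me3_{cell}.bed", "H3K27me3", cell)
        states, n_biv = call_bivalent_promoters(k4me3, k27me3, genes)
        with open(stage_dir / f"promoter_states_{cell}.tsv", "w") as fh:
            fh.write("gene_id\tH3K4me3\tH3K27me3\tbivalent\n")
            for s in states:
                fh.write(
                    f"{s.gene_id}\t{int('H3K4me3' in s.marks_present)}\t"
                    f"{int('H3K27me3' in s.marks_present)}\t{int(s.bivalent)}\n"
                )
        called = {s.gene_id for s in states if s.bivalent}
        prec, rec = precision_recall(called, truth.bivalent_genes[cell])
        fragment[f"bivalent_{cell}"] = {
            "count": n_biv,
            "precision": prec,
            "recall": rec,
        }
        fragment[f"h3k4me3_promoter_fraction_{cell}"] = \
            peak_promoter_fraction(k4me3, genes)

    # cluster classes -> per-class enhancer BED + nearest-gene sets
    assignments = _read_assignments(outdir)
    regions = _union_enhancer_candidates(simdir)
    from .tracks import ClusterResult

    labels = np.array([assignments[iv.id] for iv in regions])
    k = cfg["clustering"]["k"]
    dummy = ClusterResult(
        k=k, row_ids=[iv.id for iv in regions], labels=labels,
        centroids=np.zeros((k, 1)), seed=cfg["seed"], inertia=0.0,
    )
    class_sets = enhancer_class_sets(dummy, regions)
    from .core import TSSIndex, nearest_gene_within

    index = TSSIndex(genes)
    with open(stage_dir / "class_genes.tsv", "w") as fh:
        fh.write("class\tgene_id\n")
        for label, pset in sorted(class_sets.items()):
            write_bed(pset, stage_dir / f"enhancer_class_{label}.bed")
            gene_set = sorted({
                gid for iv in pset
                if (gid := nearest_gene_within(iv, index)) is not None
            })
            for gid in gene_set:
                fh.write(f"{label}\t{gid}\n")
    return fragment


def _stage_methylation(cfg: dict, outdir: Path) -> dict:
    simdir = outdir / "simulate"
    mcfg = cfg["methylation"]
    stage_dir = outdir / "methylation"
    genes = read_gene_models(simdir / "genes.tsv")
    truth = GroundTruth.from_json(simdir / "truth.json")
    capture = read_bedgraph(simdir / "capture_fgsc.bedgraph")
    input_track = read_bedgraph(simdir / "input_fgsc.bedgraph")
    bisulfite = BisulfiteTable.read_tsv(simdir / "bisulfite_mgsc.tsv")
    cpg_bed = read_bed(simdir / "cpgs.bed")
    cpgs = CpGIndex({
        chrom: np.array([iv.start for iv in cpg_bed if iv.chrom == chrom])
        for chrom in {iv.chrom for iv in cpg_bed}
    })
    islands = read_bed(simdir / "cpg_islands.bed", "CpG_island", "")
    transposons = read_bed(simdir / "transposons.bed", "TE", "")
    dmrs = read_bed(simdir / "dmrs.bed", "DMR", "")

    windows = promoter_windows(genes)
    cap_windows = call_capture_hmrs(
        capture, input_track, windows,
        alpha=mcfg["alpha"], min_fold=mcfg["min_fold"],
        pseudocount=mcfg["pseudocount"], cpgs=cpgs,
    )
    bis_windows = call_bisulfite_regions(
        windows, bisulfite,
        min_coverage=mcfg["min_coverage"], alpha=mcfg["alpha"],
    )
    write_methyl_windows(cap_windows, stage_dir / "promoter_windows_capture_fgsc.tsv")
    write_methyl_windows(bis_windows, stage_dir / "promoter_windows_bisulfite_mgsc.tsv")

    fragment: dict = {}
    try:
        r, n_pairs = cross_platform_correlation(cap_windows, bis_windows)
        fragment["cross_platform_pearson_r"] = r
        fragment["cross_platform_n_windows"] = n_pairs
    except (InsufficientDataError, ValueError) as exc:
        fragment["cross_platform_pearson_r"] = None
        fragment["cross_platform_error"] = str(exc)

    cap_gene = promoter_gene_calls(cap_windows)
    bis_gene = promoter_gene_calls(bis_windows)
    comparison = compare_promoter_calls(cap_gene, bis_gene)
    fragment["promoter_comparison"] = comparison.counts
    truth_sex = truth.sex_specific_methyl
    p_a, r_a = precision_recall(comparison.a_specific, truth_sex["female_only"])
    p_b, r_b = precision_recall(comparison.b_specific, truth_sex["male_only"])
    fragment["sex_specific"] = {
        "female_precision": p_a, "female_recall": r_a,
        "male_precision": p_b, "male_recall": r_b,
    }
    prec, rec = precision_recall(
        {g for g, m in cap_gene.items() if m}, truth.promoter_methyl["fgsc"]
    )
    fragment["capture_promoter_call"] = {"precision": prec, "recall": rec}
    prec, rec = precision_recall(
        {g for g, m in bis_gene.items() if m}, truth.promoter_methyl["mgsc"]
    )
    fragment["bisulfite_promoter_call"] = {"precision": prec, "recall": rec}

    # genome-wide 1-kb tiles for body/TE/DMR summaries
    tiles = tile_genome(capture.chrom_lengths, mcfg["tile_width"])
    cap_tiles = call_capture_hmrs(
        capture, input_track, tiles,
        alpha=mcfg["alpha"], min_fold=mcfg["min_fold"],
        pseudocount=mcfg["pseudocount"], cpgs=cpgs,
    )
    bis_tiles = call_bisulfite_regions(
        tiles, bisulfite, min_coverage=mcfg["min_coverage"], alpha=mcfg["alpha"]
    )
    fragment["n_hmr_tiles_fgsc"] = sum(w.is_methylated for w in cap_tiles)
    fragment["n_methylated_tiles_mgsc"] = sum(w.is_methylated for w in bis_tiles)

    body = gene_body_calls(genes, cap_tiles,
                           interior_margin=mcfg["body_interior_margin"])
    categories, frac_body = categorize_genes_by_methylation(cap_gene, body)
    with open(stage_dir / "gene_methylation_categories_fgsc.tsv", "w") as fh:
        fh.write("gene_id\tcategory\n")
        for gid in sorted(categories):
            fh.write(f"{gid}\t{categories[gid]}\n")
    counts = {cat: 0 for cat in ("promoter_methylated", "body_only",
                                 "hypomethylated")}
    for cat in categories.values():
        counts[cat] += 1
    fragment["gene_categories_fgsc"] = counts
    fragment["fraction_promoter_methylated_with_body"] = frac_body

    te_freq = {
        "fgsc": annotation_methylation_frequency(
            transposons, cap_tiles, require_cpg_island_overlap=True,
            cpg_islands=islands),
        "mgsc": annotation_methylation_frequency(
            transposons, bis_tiles, require_cpg_island_overlap=True,
            cpg_islands=islands),
    }
    fragment["te_methylation_frequency"] = {
        cell: {fam: {"frequency": v[0], "n_loci": v[1]}
               for fam, v in freqs.items()}
        for cell, freqs in te_freq.items()
    }
    with open(stage_dir / "te_methylation_frequency.tsv", "w") as fh:
        fh.write("family\tcell\tfrequency\tn_loci\n")
        for cell, freqs in sorted(te_freq.items()):
            for fam, (freq, n) in sorted(freqs.items()):
                val = "" if freq is None else f"{freq:.4f}"
                fh.write(f"{fam}\t{cell}\t{val}\t{n}\n")

    dmr_status = locus_methylation_status(
        dmrs, {"fgsc": cap_tiles, "mgsc": bis_tiles}
    )
    dmr_status.to_csv(stage_dir / "dmr_status.tsv", sep="\t", index=False)
    n_match = 0
    for _, row in dmr_status.iterrows():
        planted = truth.dmr_states.get(row["locus"])
        expected = (planted == "female_only", planted == "male_only")
        n_match += (bool(row["fgsc"]), bool(row["mgsc"])) == expected
    fragment["dmr_pattern_match"] = {
        "n_match": int(n_match), "n_total": int(len(dmr_status))
    }
    return fragment


def _stage_integration(cfg: dict, outdir: Path) -> dict:
    simdir = outdir / "simulate"
    ecfg = cfg["expression"]
    stage_dir = outdir / "integration"
    expr = ExpressionTable.read_tsv(simdir / "expression.tsv")
    truth = GroundTruth.from_json(simdir / "truth.json")
    class_genes = pd.read_csv(outdir / "chromatin" / "class_genes.tsv", sep="\t")
    gene_sets = {
        f"enhancer_class_{label}": sorted(sub["gene_id"])
        for label, sub in class_genes.groupby("class")
    }
    comparisons = class_expression_comparison(expr, gene_sets, "fgsc", "esc")
    fragment: dict = {"expression_comparisons": {}}
    with open(stage_dir / "expression_comparisons.tsv", "w") as fh:
        fh.write("class\tn\tstatistic\tp_value\tmedian_fgsc\tmedian_esc\n")
        for comp in comparisons:
            name = comp.summary.get("class", "?")
            fh.write(
                f"{name}\t{comp.n}\t{comp.statistic:.6g}\t{comp.p_value:.6g}\t"
                f"{comp.summary.get('median_a', float('nan')):.6g}\t"
                f"{comp.summary.get('median_b', float('nan')):.6g}\n"
            )
            fragment["expression_comparisons"][name] = {
                "n": comp.n,
                "p_value": comp.p_value,
                "median_fgsc": comp.summary.get("median_a"),
                "median_esc": comp.summary.get("median_b"),
                "test": comp.test_name,
            }

    # knockdown differential expression (kd vs control, single libraries)
    kd = expr.column("fgsc_kd", counts=True).astype(int)
    ctrl = expr.column("fgsc", counts=True).astype(int)
    de = two_library_de(kd, ctrl, alpha=ecfg["alpha"], genes=expr.genes)
    de.to_csv(stage_dir / "knockdown_de.tsv", sep="\t")
    up = set(de.index[(de["significant"]) & (de["direction"] == "a_up")])
    prec, rec = precision_recall(up, truth.knockdown_genes)
    fragment["knockdown_de"] = {
        "n_up": len(up),
        "n_planted_responsive": len(truth.knockdown_genes),
        "precision": prec,
        "recall": rec,
    }
    return fragment


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_pipeline(config, outdir) -> dict:
    """Execute all stages into ``outdir`` and return the summary dict.

    ``config`` is a YAML path or a dict (missing sections take defaults).
    Stage outputs are cached by input digest: rerunning without changes is a
    no-op, and removing one stage's outputs recomputes only that stage and
    its dependents.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"

    def log(message: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        with open(log_path, "a") as fh:
            fh.write(f"{stamp} {message}\n")

    log(f"pipeline start: version={__version__} seed={cfg['seed']}")
    stages = _Stage(outdir, log)

    d_sim = _digest({"seed": cfg["seed"], "simulation": cfg["simulation"]})
    frag_sim = stages.run(
        "simulate", d_sim,
        [outdir / "simulate" / "truth.json",
         outdir / "simulate" / "expression.tsv"],
        lambda: _stage_simulate(cfg, outdir),
    )
    d_clu = _digest({"up": d_sim, "clustering": cfg["clustering"]})
    frag_clu = stages.run(
        "cluster", d_clu,
        [outdir / "cluster" / "assignments.tsv"],
        lambda: _stage_cluster(cfg, outdir),
    )
    d_chr = _digest({"up": [d_sim, d_clu], "chromatin": cfg["chromatin"]})
    frag_chr = stages.run(
        "chromatin", d_chr,
        [outdir / "chromatin" / "class_genes.tsv"],
        lambda: _stage_chromatin(cfg, outdir),
    )
    d_met = _digest({"up": d_sim, "methylation": cfg["methylation"]})
    frag_met = stages.run(
        "methylation", d_met,
        [outdir / "methylation" / "dmr_status.tsv"],
        lambda: _stage_methylation(cfg, outdir),
    )
    d_int = _digest({"up": [d_sim, d_chr], "expression": cfg["expression"]})
    frag_int = stages.run(
        "integration", d_int,
        [outdir / "integration" / "knockdown_de.tsv"],
        lambda: _stage_integration(cfg, outdir),
    )

    summary = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "simulate": frag_sim,
        "cluster": frag_clu,
        "chromatin": frag_chr,
        "methylation": frag_met,
        "integration": frag_int,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
        fh.write("\n")
    log("pipeline done")
    return summary
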