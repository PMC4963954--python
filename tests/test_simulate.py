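"""Synthetic-data generator: determinism, planted structure, file validity."""

import numpy as np
import pytest

from epigsc.core import read_bed, read_gene_models
from epigsc.methylation import BisulfiteTable
from epigsc.simulate import (
    SimulationConfig,
    SizingError,
    cpg_methylation_states,
    generate_chip_assay,
    generate_expression,
    generate_genome,
    generate_methylation_assays,
    simulate,
    write_simulation,
)
from epigsc.stats import ExpressionTable, paired_wilcoxon
from epigsc.tracks import read_bedgraph
from conftest import small_config


class TestGenomeLayout:
    def test_deterministic_under_seed(self):
        g1, t1 = generate_genome(small_config(seed=5))
        g2, t2 = generate_genome(small_config(seed=5))
        assert g1.genes == g2.genes
        assert np.array_equal(g1.cpgs.pos["chrS"], g2.cpgs.pos["chrS"])
        assert t1.enhancer_classes == t2.enhancer_classes
        assert t1.promoter_methyl == t2.promoter_methyl

    def test_no_genes_no_features(self):
        cfg = SimulationConfig(
            seed=1, n_genes=0, n_enhancers_per_class=0, n_te_per_family=0,
            n_dmrs=0, n_body_only_genes=0, n_knockdown_responsive=0,
            n_bivalent={}, n_repressed={}, n_silent={},
        )
        genome, truth = generate_genome(cfg)
        assert genome.genes == []
        assert len(genome.enhancers) == 0
        assert truth.promoter_methyl == {"fgsc": set(), "mgsc": set()}

    def test_overfull_genome_rejected(self):
        with pytest.raises(SizingError):
            generate_genome(small_config(genome_length=500_000))  # slots < 18 kb
        with pytest.raises(SizingError):
            generate_genome(small_config(n_enhancers_per_class=50))

    def test_gene_bodies_disjoint_and_promoters_in_bounds(self):
        genome, _ = generate_genome(small_config())
        genes = sorted(genome.genes, key=lambda g: g.body_start)
        for a, b in zip(genes, genes[1:]):
            assert a.body_end <= b.body_start
        for g in genome.genes:
            assert g.promoter.start >= 0
            assert g.promoter.end <= genome.chrom_lengths[g.chrom]

    def test_enhancers_distal_to_every_tss(self):
        genome, _ = generate_genome(small_config())
        tss = np.array([g.tss for g in genome.genes])
        for iv in genome.enhancers:
            assert np.abs(tss - iv.center).min() > 2000

    def test_truth_partitions_domains(self):
        genome, truth = generate_genome(small_config())
        classes = list(truth.enhancer_classes.values())
        assert len(truth.enhancer_classes) == len(genome.enhancers)
        assert set(classes) <= {"shared", "fgsc_specific", "esc_specific",
                                "weak"}
        sex = truth.sex_specific_methyl
        gene_ids = {g.gene_id for g in genome.genes}
        parts = [sex["female_only"], sex["male_only"], sex["both"],
                 sex["neither"]]
        assert set().union(*parts) == gene_ids
        assert sum(len(p) for p in parts) == len(gene_ids)  # disjoint


class TestChipAssay:
    def test_track_and_peaks_consistent(self, small_sim):
        peaks, track = small_sim.chip[("H3K4me1", "fgsc")]
        rpkm = track.rpkm("chrS")
        bw = track.bin_width
        for iv in peaks:
            b0, b1 = iv.start // bw, (iv.end - 1) // bw
            in_peak = rpkm[b0:b1 + 1].mean()
            flank = np.concatenate([
                rpkm[max(b0 - 40, 0):max(b0 - 20, 0)],
                rpkm[b1 + 20:b1 + 40],
            ]).mean()
            assert in_peak > flank

    def test_noise_free_limit_elevated_exactly_over_peaks(self):
        cfg = small_config(noise_dispersion=0.0)
        genome, truth = generate_genome(cfg)
        peaks, track = generate_chip_assay(cfg, genome, truth, "H3K27ac",
                                           "fgsc")
        counts = track.counts("chrS")
        bw = cfg.bin_width
        peak_bins = set()
        for iv in peaks:
            peak_bins.update(range(iv.start // bw, (iv.end - 1) // bw + 1))
        bg = np.array([c for i, c in enumerate(counts) if i not in peak_bins])
        # Poisson background mean ~1; peak bins have mean ~21
        assert bg.mean() < 3
        in_peak = np.array([counts[i] for i in sorted(peak_bins)])
        assert in_peak.mean() > 10 * bg.mean()

    def test_same_seed_identical_track(self):
        cfg = small_config(seed=9)
        genome, truth = generate_genome(cfg)
        _, t1 = generate_chip_assay(cfg, genome, truth, "H3K4me3", "esc")
        _, t2 = generate_chip_assay(cfg, genome, truth, "H3K4me3", "esc")
        assert np.array_equal(t1.data["chrS"], t2.data["chrS"])

    def test_unknown_mark_or_cell_rejected(self, small_sim_config):
        genome, truth = generate_genome(small_sim_config)
        with pytest.raises(ValueError):
            generate_chip_assay(small_sim_config, genome, truth, "H3K9me3",
                                "fgsc")
        with pytest.raises(ValueError):
            generate_chip_assay(small_sim_config, genome, truth, "H3K4me1",
                                "npc")

    def test_threshold_recovery_at_low_dispersion(self):
        """At dispersion 0.05 a plain signal threshold recovers >= 99 % of
        planted peaks."""
        cfg = small_config(noise_dispersion=0.05)
        genome, truth = generate_genome(cfg)
        peaks, track = generate_chip_assay(cfg, genome, truth, "H3K4me1",
                                           "fgsc")
        counts = track.counts("chrS")
        # background is ~1 expected read/bin; call a peak recovered when its
        # mean count clears 4x that (weak peaks sit at ~9 reads/bin)
        threshold = 4 * np.median(counts[counts > 0])
        bw = cfg.bin_width
        recovered = 0
        for iv in peaks:
            b0, b1 = iv.start // bw, (iv.end - 1) // bw
            recovered += counts[b0:b1 + 1].mean() > threshold
        assert recovered / len(peaks) >= 0.99


class TestMethylationAssays:
    def test_capture_tracks_deterministic(self, small_sim_config):
        genome, truth = generate_genome(small_sim_config)
        a = generate_methylation_assays(small_sim_config, genome, truth)
        b = generate_methylation_assays(small_sim_config, genome, truth)
        assert np.array_equal(a.capture_fgsc.data["chrS"],
                              b.capture_fgsc.data["chrS"])
        assert np.array_equal(a.bisulfite_mgsc.count_C["chrS"],
                              b.bisulfite_mgsc.count_C["chrS"])

    def test_bisulfite_means_near_beta_params(self, small_sim,
                                              small_sim_config):
        cfg = small_sim_config
        genome, truth = small_sim.genome, small_sim.truth
        table = small_sim.methylation.bisulfite_mgsc
        state = cpg_methylation_states(cfg, genome, truth, "mgsc")
        pos_all = genome.cpgs.pos["chrS"]
        state_by_pos = dict(zip(pos_all.tolist(), state.tolist()))
        pos = table.pos["chrS"]
        c = table.count_C["chrS"].astype(float)
        t = table.count_T["chrS"].astype(float)
        meth = np.array([state_by_pos[p] for p in pos.tolist()])
        ratio_meth = c[meth].sum() / (c[meth] + t[meth]).sum()
        ratio_unmeth = c[~meth].sum() / (c[~meth] + t[~meth]).sum()
        mu_m, mu_u = cfg.methyl_beta_params
        assert ratio_meth == pytest.approx(mu_m, abs=0.03)
        assert ratio_unmeth == pytest.approx(mu_u, abs=0.02)

    def test_capture_signal_tracks_methylated_cpgs(self, small_sim,
                                                   small_sim_config):
        cfg = small_sim_config
        genome, truth = small_sim.genome, small_sim.truth
        cap = small_sim.methylation.capture_fgsc
        state = cpg_methylation_states(cfg, genome, truth, "fgsc")
        pos = genome.cpgs.pos["chrS"]
        counts = cap.counts("chrS")
        nbins = len(counts)
        meth_bins = np.unique(pos[state] // cfg.bin_width)
        meth_mask = np.zeros(nbins, dtype=bool)
        meth_mask[meth_bins] = True
        assert counts[meth_mask].mean() > 10 * counts[~meth_mask].mean()


class TestExpression:
    def test_methylated_promoters_lower_in_fgsc(self, small_sim):
        expr = small_sim.expression
        truth = small_sim.truth
        meth = truth.promoter_methyl["fgsc"]
        fgsc = expr.column("fgsc")
        meth_mask = np.array([g in meth for g in expr.genes])
        assert np.median(fgsc[meth_mask]) < np.median(fgsc[~meth_mask]) / 2

    def test_ratio_one_removes_methylation_effect(self):
        cfg = small_config(seed=23, n_genes=120, genome_length=2_400_000,
                           methylation_expression_ratio=1.0,
                           enhancer_expression_fold=1.0,
                           n_enhancers_per_class=10)
        sim_genome, truth = generate_genome(cfg)
        expr = generate_expression(cfg, sim_genome, truth)
        meth = truth.promoter_methyl["fgsc"]
        mask = np.array([g in meth for g in expr.genes])
        res = paired_wilcoxon(
            np.log1p(expr.column("fgsc")[mask][:60]),
            np.log1p(expr.column("esc")[mask][:60]),
        )
        assert res.p_value > 0.05

    def test_zero_depth_zero_counts(self, small_sim_config):
        cfg = small_config(expression_depth_per_fpkm=0.0)
        genome, truth = generate_genome(cfg)
        expr = generate_expression(cfg, genome, truth)
        assert np.all(expr.counts == 0)

    def test_knockdown_genes_boosted(self, small_sim):
        expr = small_sim.expression
        truth = small_sim.truth
        kd_mask = np.array([g in truth.knockdown_genes for g in expr.genes])
        ratio = expr.column("fgsc_kd") / np.maximum(expr.column("fgsc"), 1e-9)
        assert np.median(ratio[kd_mask]) >= 2.0
        # non-responsive genes keep only independent condition noise
        assert np.median(ratio[~kd_mask]) == pytest.approx(1.0, abs=0.1)


class TestBundleRoundtrip:
    def test_written_files_validate_against_readers(self, small_sim, tmp_path):
        write_simulation(small_sim, tmp_path)
        genes = read_gene_models(tmp_path / "genes.tsv")
        assert genes == small_sim.genome.genes
        peaks = read_bed(tmp_path / "peaks_H3K4me1_fgsc.bed")
        assert len(peaks) == len(small_sim.chip[("H3K4me1", "fgsc")][0])
        track = read_bedgraph(tmp_path / "track_H3K4me1_fgsc.bedgraph")
        orig = small_sim.chip[("H3K4me1", "fgsc")][1]
        assert track.library_size == orig.library_size
        assert track.data["chrS"] == pytest.approx(orig.data["chrS"],
                                                   rel=1e-4, abs=1e-8)
        table = BisulfiteTable.read_tsv(tmp_path / "bisulfite_mgsc.tsv")
        assert table.n_sites == small_sim.methylation.bisulfite_mgsc.n_sites
        expr = ExpressionTable.read_tsv(tmp_path / "expression.tsv")
        assert expr.genes == small_sim.expression.genes

    def test_two_writes_byte_identical(self, tmp_path):
        cfg = small_config(seed=31)
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        write_simulation(simulate(cfg), a_dir)
        write_simulation(simulate(cfg), b_dir)
        for path_a in sorted(a_dir.iterdir()):
            path_b = b_dir / path_a.name
            assert path_a.read_bytes() == path_b.read_bytes(), path_a.name
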