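"""Methylation scoring, exact-binomial calling, BH and comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epigsc.core import GeneModel, GenomicInterval, PeakSet
from epigsc.methylation import (
    BisulfiteSite,
    BisulfiteTable,
    CpGIndex,
    InsufficientDataError,
    MethylWindow,
    annotation_methylation_frequency,
    bh_adjust,
    binomial_methylation_call,
    bisulfite_ams,
    call_bisulfite_regions,
    call_capture_hmrs,
    capture_rms,
    categorize_genes_by_methylation,
    compare_promoter_calls,
    cross_platform_correlation,
    gene_body_calls,
    promoter_gene_calls,
    promoter_windows,
    tile_genome,
)
from epigsc.tracks import track_from_counts


def binom_tail_oracle(c, n, p0):
    """Brute-force upper tail by pmf summation with exact binomials."""
    return sum(
        math.comb(n, k) * p0 ** k * (1 - p0) ** (n - k) for k in range(c, n + 1)
    )


def bh_oracle(p):
    """Literal BH step-up: q(i) = min_{j>=i} p(j) * m / j on sorted p."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestWindows:
    GENES = [
        GeneModel("gp", "chr1", "+", 10_000, 10_000, 20_000),
        GeneModel("gm", "chr1", "-", 49_999, 40_000, 50_000),
    ]

    def test_plus_strand_windows(self):
        wins = [w for w in promoter_windows(self.GENES) if "gp" in w.name]
        assert [(w.start, w.end) for w in wins] == [
            (8000, 8500), (8500, 9000), (9000, 9500), (9500, 10_000),
            (10_000, 10_500),
        ]
        assert [w.name for w in wins] == [f"gp:{i}" for i in range(1, 6)]

    def test_minus_strand_mirrors(self):
        wins = [w for w in promoter_windows(self.GENES) if "gm" in w.name]
        # window 1 is most upstream = highest coordinates
        assert wins[0].end == 49_999 + 2001
        assert wins[-1].start == 49_999 - 499
        assert len({w.start for w in wins}) == 5

    def test_window_count(self):
        assert len(promoter_windows(self.GENES)) == 5 * len(self.GENES)

    def test_tiling_covers_and_truncates(self):
        tiles = tile_genome({"c": 2500}, 1000)
        assert [(t.start, t.end) for t in tiles] == \
            [(0, 1000), (1000, 2000), (2000, 2500)]
        tiles = tile_genome({"c": 700}, 1000)
        assert [(t.start, t.end) for t in tiles] == [(0, 700)]


class TestScores:
    def test_rms_formula(self):
        # one 500-bp window with 100 of the library's 1e6 reads:
        # RPKM = 100 / (0.5 * 1) = 200; with 4 CpGs rms = 50
        counts = np.zeros(200)
        counts[:10] = 10.0
        filler = np.full(19_800, (1e6 - 100) / 19_800)
        track = track_from_counts(
            {"chr1": np.concatenate([counts, filler])},
            {"chr1": 1_000_000}, 50)
        track.library_size = 1_000_000
        window = GenomicInterval("chr1", 0, 500)
        cpgs = CpGIndex({"chr1": [10, 20, 30, 40]})
        mw = capture_rms(window, track, cpgs)
        assert mw.score == pytest.approx(200.0 / 4, rel=1e-3)
        assert mw.cpg_count == 4

    def test_rms_no_cpgs_is_no_data(self):
        track = track_from_counts({"chr1": np.ones(20)}, {"chr1": 1000}, 50)
        mw = capture_rms(GenomicInterval("chr1", 0, 500), track,
                         CpGIndex({"chr1": []}))
        assert mw.call == "no_data"

    def test_ams_pools_counts(self):
        table = BisulfiteTable([
            BisulfiteSite("chr1", 100, "+", 9, 1),
            BisulfiteSite("chr1", 200, "+", 3, 7),
        ])
        mw = bisulfite_ams(GenomicInterval("chr1", 0, 500), table)
        assert mw.score == pytest.approx(0.6)
        assert mw.coverage == 20

    def test_ams_all_converted_is_zero(self):
        table = BisulfiteTable([BisulfiteSite("chr1", 100, "+", 0, 15)])
        mw = bisulfite_ams(GenomicInterval("chr1", 0, 500), table)
        assert mw.score == 0.0

    def test_ams_low_coverage_no_data(self):
        table = BisulfiteTable([BisulfiteSite("chr1", 100, "+", 2, 1)])
        mw = bisulfite_ams(GenomicInterval("chr1", 0, 500), table,
                           min_coverage=10)
        assert mw.call == "no_data"

    @given(st.integers(0, 30), st.integers(0, 30))
    def test_ams_invariant_to_splitting_site_records(self, c, t):
        whole = BisulfiteTable([BisulfiteSite("chr1", 100, "+", c, t)])
        split = BisulfiteTable([
            BisulfiteSite("chr1", 100, "+", c - c // 2, t - t // 2),
            BisulfiteSite("chr1", 100, "+", c // 2, t // 2),
        ])
        w = GenomicInterval("chr1", 0, 500)
        a = bisulfite_ams(w, whole, min_coverage=0)
        b = bisulfite_ams(w, split, min_coverage=0)
        if c + t > 0:
            assert a.score == pytest.approx(b.score)
        assert a.coverage == b.coverage


class TestBinomialCall:
    def test_stated_example(self):
        assert binomial_methylation_call(6, 10, 0.25) == \
            pytest.approx(0.019727, abs=1e-6)

    def test_zero_count_whole_tail(self):
        assert binomial_methylation_call(0, 10, 0.25) == pytest.approx(1.0)

    def test_all_methylated_closed_form(self):
        assert binomial_methylation_call(4, 4, 0.25) == \
            pytest.approx(0.25 ** 4, rel=1e-12)

    @given(st.integers(1, 25), st.data())
    def test_matches_pmf_enumeration(self, n, data):
        c = data.draw(st.integers(0, n))
        for p0 in (0.25, 0.75):
            assert binomial_methylation_call(c, n, p0) == \
                pytest.approx(binom_tail_oracle(c, n, p0), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            binomial_methylation_call(1, 0, 0.25)
        with pytest.raises(ValueError):
            binomial_methylation_call(1, 10, 1.5)


class TestBH:
    def test_hand_worked_example(self):
        q = bh_adjust([0.001, 0.02, 0.04, 0.2])
        assert q == pytest.approx([0.004, 0.04, 0.04 * 4 / 3, 0.2])

    def test_single_and_tied(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_matches_brute_force_and_permutation_invariant(self, p):
        q = bh_adjust(p)
        assert q == pytest.approx(bh_oracle(p), abs=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15)  # q >= p under BH
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        q_perm = bh_adjust([p[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm], abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _uniform_windows(n, width=500):
    return [GenomicInterval("chr1", i * width, (i + 1) * width, name=f"g{i}:1")
            for i in range(n)]


class TestBisulfiteCalling:
    def _table(self, per_window):
        """per_window: list of (C, T) placed one site per window."""
        sites = [
            BisulfiteSite("chr1", i * 500 + 250, "+", c, t)
            for i, (c, t) in enumerate(per_window)
        ]
        return BisulfiteTable(sites)

    def test_high_ratio_called_highly_methylated(self):
        spec = [(95, 5)] + [(10, 90)] * 99
        calls = call_bisulfite_regions(_uniform_windows(100),
                                       self._table(spec))
        assert calls[0].call == "highly_methylated"
        assert calls[0].q_value_high < 0.01

    def test_low_ratio_unmethylated(self):
        spec = [(10, 90)] * 100
        calls = call_bisulfite_regions(_uniform_windows(100),
                                       self._table(spec))
        assert all(c.call == "unmethylated" for c in calls)

    def test_intermediate_ratio_methylated_only(self):
        spec = [(50, 50)] + [(10, 90)] * 99
        calls = call_bisulfite_regions(_uniform_windows(100),
                                       self._table(spec))
        assert calls[0].call == "methylated"

    def test_low_coverage_no_data(self):
        spec = [(2, 1)] + [(10, 90)] * 9
        calls = call_bisulfite_regions(_uniform_windows(10),
                                       self._table(spec), min_coverage=10)
        assert calls[0].call == "no_data"
        assert calls[0].p_value is None

    def test_highly_implies_methylated_test_would_pass(self):
        spec = [(90, 10), (80, 20), (30, 70), (5, 95)] + [(10, 90)] * 46
        calls = call_bisulfite_regions(_uniform_windows(50),
                                       self._table(spec))
        for c in calls:
            if c.call == "highly_methylated":
                assert c.q_value < 0.01  # the 0.25-family also rejects


class TestCaptureHmrs:
    def _tracks(self, cap_counts, in_counts, length):
        cap = track_from_counts({"chr1": np.asarray(cap_counts, float)},
                                {"chr1": length}, 50)
        inp = track_from_counts({"chr1": np.asarray(in_counts, float)},
                                {"chr1": length}, 50)
        return cap, inp

    def test_identical_tracks_never_called(self):
        counts = np.full(200, 10.0)
        cap, inp = self._tracks(counts, counts, 10_000)
        tiles = tile_genome({"chr1": 10_000}, 1000)
        calls = call_capture_hmrs(cap, inp, tiles)
        assert not any(c.is_methylated for c in calls)
        assert all(c.fold == pytest.approx(1.0, rel=0.01) for c in calls
                   if c.fold is not None)

    def test_strong_enrichment_called(self):
        cap_counts = np.full(200, 5.0)
        in_counts = np.full(200, 5.0)
        cap_counts[:20] = 105.0  # tile 0 capture count 2100 vs input 100
        cap, inp = self._tracks(cap_counts, in_counts, 10_000)
        tiles = tile_genome({"chr1": 10_000}, 1000)
        calls = call_capture_hmrs(cap, inp, tiles)
        assert calls[0].call == "highly_methylated"
        assert calls[0].fold > 2
        assert not any(c.is_methylated for c in calls[1:])

    def test_adding_capture_reads_never_uncalls(self):
        cap_counts = np.full(100, 5.0)
        cap_counts[:20] = 50.0
        in_counts = np.full(100, 5.0)
        tiles = tile_genome({"chr1": 5000}, 1000)
        cap, inp = self._tracks(cap_counts, in_counts, 5000)
        base = call_capture_hmrs(cap, inp, tiles)
        boosted_counts = cap_counts.copy()
        boosted_counts[:20] += 30.0
        cap2, _ = self._tracks(boosted_counts, in_counts, 5000)
        more = call_capture_hmrs(cap2, inp, tiles)
        if base[0].is_methylated:
            assert more[0].is_methylated

    def test_missing_library_size_rejected(self):
        cap, inp = self._tracks(np.ones(20), np.zeros(20), 1000)
        with pytest.raises(ValueError):
            call_capture_hmrs(cap, inp, tile_genome({"chr1": 1000}, 1000))


class TestCrossPlatform:
    def _wins(self, scores, assay):
        return [
            MethylWindow(GenomicInterval("chr1", i * 500, (i + 1) * 500,
                                         name=f"g{i}:1"), assay, s, 50, 5)
            for i, s in enumerate(scores)
        ]

    def test_identical_vectors_r_one(self):
        cap = self._wins([1.0, 2.0, 3.0, 4.0], "capture")
        bis = self._wins([1.0, 2.0, 3.0, 4.0], "bisulfite")
        r, n = cross_platform_correlation(cap, bis)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_constant_vector_rejected(self):
        cap = self._wins([1.0, 1.0, 1.0], "capture")
        bis = self._wins([0.2, 0.5, 0.9], "bisulfite")
        with pytest.raises(ValueError, match="constant"):
            cross_platform_correlation(cap, bis)

    def test_no_data_pairs_dropped(self):
        cap = self._wins([1.0, 2.0, 3.0, 4.0, 5.0], "capture")
        bis = self._wins([1.0, 2.0, 3.0, 4.0, 5.0], "bisulfite")
        bis[0].call = "no_data"
        r, n = cross_platform_correlation(cap, bis)
        assert n == 4

    def test_insufficient_pairs_rejected(self):
        cap = self._wins([1.0, 2.0], "capture")
        bis = self._wins([1.0, 2.0], "bisulfite")
        with pytest.raises(InsufficientDataError):
            cross_platform_correlation(cap, bis)


class TestGeneLevel:
    def _win(self, name, call):
        return MethylWindow(GenomicInterval("c", 0, 500, name=name),
                            "bisulfite", 0.5, 100, 5, call=call)

    def test_any_window_rule(self):
        wins = [self._win("g1:1", "unmethylated"),
                self._win("g1:2", "methylated"),
                self._win("g2:1", "unmethylated"),
                self._win("g2:2", "no_data")]
        calls = promoter_gene_calls(wins)
        assert calls == {"g1": True, "g2": False}

    def test_comparison_partition(self):
        a = {"g1": True, "g2": True, "g3": False, "g4": True}
        b = {"g1": True, "g2": False, "g3": True, "g4": False}
        comp = compare_promoter_calls(a, b)
        assert comp.shared == {"g1"}
        assert comp.a_specific == {"g2", "g4"}
        assert comp.b_specific == {"g3"}
        total = len(comp.shared | comp.a_specific | comp.b_specific)
        assert total == len({g for g in a if a[g] or b[g]})

    def test_categorize_precedence(self):
        prom = {"g1": True, "g2": False, "g3": False}
        body = {"g1": True, "g2": True, "g3": False}
        cats, frac = categorize_genes_by_methylation(prom, body)
        assert cats == {"g1": "promoter_methylated", "g2": "body_only",
                        "g3": "hypomethylated"}
        assert frac == 1.0

    def test_body_calls_fully_within_interior(self):
        gene = GeneModel("g", "chr1", "+", 10_000, 10_000, 20_000)
        inside = MethylWindow(GenomicInterval("chr1", 14_000, 15_000),
                              "capture", 1.0, 10, 5, call="highly_methylated")
        straddling = MethylWindow(GenomicInterval("chr1", 10_500, 11_500),
                                  "capture", 1.0, 10, 5,
                                  call="highly_methylated")
        assert gene_body_calls([gene], [inside], interior_margin=1000)["g"]
        assert not gene_body_calls([gene], [straddling],
                                   interior_margin=1000)["g"]
        # plain-overlap mode accepts the straddling tile
        assert gene_body_calls([gene], [straddling])["g"]


class TestAnnotationFrequency:
    def _calls(self, ivs):
        return [MethylWindow(iv, "capture", 1.0, 10, 5,
                             call="highly_methylated") for iv in ivs]

    def test_full_overlap_is_one_and_empty_is_none(self):
        tes = PeakSet("TE", "", [
            GenomicInterval("chr1", 0, 500, name="LINE_L1"),
            GenomicInterval("chr1", 1000, 1500, name="LINE_L1"),
        ])
        calls = self._calls([GenomicInterval("chr1", 0, 2000)])
        freq = annotation_methylation_frequency(tes, calls)
        assert freq["LINE_L1"] == (1.0, 2)
        empty = PeakSet("TE", "", [])
        assert annotation_methylation_frequency(empty, calls) == {}

    def test_island_restriction_shrinks_denominator(self):
        tes = PeakSet("TE", "", [
            GenomicInterval("chr1", 0, 500, name="IAP"),
            GenomicInterval("chr1", 1000, 1500, name="IAP"),
            GenomicInterval("chr1", 2000, 2500, name="IAP"),
        ])
        islands = PeakSet("CpG", "", [GenomicInterval("chr1", 100, 200)])
        calls = self._calls([GenomicInterval("chr1", 0, 500)])
        unrestricted = annotation_methylation_frequency(tes, calls)
        restricted = annotation_methylation_frequency(
            tes, calls, require_cpg_island_overlap=True, cpg_islands=islands)
        assert unrestricted["IAP"][1] == 3
        assert restricted["IAP"] == (1.0, 1)
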