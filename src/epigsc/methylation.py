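"""Window-based DNA methylation quantification, calling and comparison.

Two assay families are supported:

* **Capture** (MethylCap/MeDIP-style enrichment): per-window signal is the
  *relative methylation score* (rms), the window RPKM divided by the number
  of CpGs in the window, so that enrichment is normalised for local CpG
  density.  Highly methylated regions (HMRs) are called per window by an
  exact binomial test of the capture read count against the matched input
  library, combined with a fold-change threshold.

* **Bisulfite**: per-window signal is the *absolute methylation signal*
  (ams), the pooled ratio sum(C) / sum(C + T) over the window's CpGs, where
  C counts unconverted (methylated) and T converted reads.  Windows are
  called *methylated* when the ratio is significantly above 0.25 and
  *highly methylated* when significantly above 0.75, each by a one-sided
  exact binomial test with Benjamini-Hochberg FDR control at 0.01.

Because rms and ams live on different scales, cross-platform comparison is
done per window with the Pearson correlation over windows where both assays
have data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BedParseError, GeneModel, GenomicInterval, PeakSet
from .tracks import BinnedTrack

UNMETHYLATED = "unmethylated"
METHYLATED = "methylated"
HIGHLY_METHYLATED = "highly_methylated"
NO_DATA = "no_data"

#: calls counted as "methylated or higher"
METHYLATED_CALLS = frozenset({METHYLATED, HIGHLY_METHYLATED})


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class BisulfiteSite:
    """Per-CpG bisulfite counts: C = unconverted (methylated evidence),
    T = converted.  Position is 0-based after reader conversion."""

    chrom: str
    pos: int
    strand: str
    count_C: int
    count_T: int

    def __post_init__(self):
        if self.count_C < 0 or self.count_T < 0:
            raise ValueError("negative bisulfite counts")

    @property
    def coverage(self) -> int:
        return self.count_C + self.count_T


class BisulfiteTable:
    """Column-oriented store of bisulfite sites with fast window queries."""

    def __init__(self, sites: Iterable[BisulfiteSite]):
        by_chrom: dict[str, list[BisulfiteSite]] = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append(s)
        self.pos: dict[str, np.ndarray] = {}
        self.count_C: dict[str, np.ndarray] = {}
        self.count_T: dict[str, np.ndarray] = {}
        self.n_sites = 0
        for chrom, ss in by_chrom.items():
            ss.sort(key=lambda s: s.pos)
            self.pos[chrom] = np.array([s.pos for s in ss], dtype=np.int64)
            self.count_C[chrom] = np.array([s.count_C for s in ss], dtype=np.int64)
            self.count_T[chrom] = np.array([s.count_T for s in ss], dtype=np.int64)
            self.n_sites += len(ss)

    @classmethod
    def from_arrays(cls, chrom: str, pos, count_C, count_T) -> "BisulfiteTable":
        """Build directly from parallel arrays for one chromosome (must be
        position-sorted)."""
        table = cls([])
        pos = np.asarray(pos, dtype=np.int64)
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted")
        table.pos[chrom] = pos
        table.count_C[chrom] = np.asarray(count_C, dtype=np.int64)
        table.count_T[chrom] = np.asarray(count_T, dtype=np.int64)
        if np.any(table.count_C[chrom] < 0) or np.any(table.count_T[chrom] < 0):
            raise ValueError("negative bisulfite counts")
        table.n_sites = len(pos)
        return table

    @classmethod
    def read_tsv(cls, path) -> "BisulfiteTable":
        """Read `chrom pos strand count_C count_T` (1-based positions)."""
        sites = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["chrom", "pos", "strand", "count_C", "count_T"]:
                raise BedParseError(path, 1, f"unexpected header {header}")
            for lineno, raw in enumerate(fh, start=2):
                line = raw.rstrip("\n")
                if not line:
                    continue
                f = line.split("\t")
                if len(f) != 5:
                    raise BedParseError(path, lineno, "expected 5 columns")
                try:
                    sites.append(
                        BisulfiteSite(f[0], int(f[1]) - 1, f[2], int(f[3]), int(f[4]))
                    )
                except ValueError as exc:
                    raise BedParseError(path, lineno, str(exc))
        return cls(sites)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tstrand\tcount_C\tcount_T\n")
            for chrom in sorted(self.pos):
                for p, c, t in zip(self.pos[chrom], self.count_C[chrom],
                                   self.count_T[chrom]):
                    fh.write(f"{chrom}\t{p + 1}\t+\t{c}\t{t}\n")

    def window_counts(self, window: GenomicInterval) -> tuple[int, int, int]:
        """(sum C, sum T, number of covered sites) inside the window."""
        pos = self.pos.get(window.chrom)
        if pos is None:
            return 0, 0, 0
        lo = int(np.searchsorted(pos, window.start, side="left"))
        hi = int(np.searchsorted(pos, window.end, side="left"))
        c = int(self.count_C[window.chrom][lo:hi].sum())
        t = int(self.count_T[window.chrom][lo:hi].sum())
        return c, t, hi - lo


@dataclass
class MethylWindow:
    """A scored (and possibly called) methylation window."""

    interval: GenomicInterval
    assay: str  # capture | bisulfite
    score: float  # rms (capture) or ams (bisulfite); nan when no data
    coverage: int
    cpg_count: int
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    call: str = UNMETHYLATED
    # second test family for bisulfite (ratio > 0.75) and capture fold change
    p_value_high: Optional[float] = None
    q_value_high: Optional[float] = None
    fold: Optional[float] = None

    @property
    def id(self) -> str:
        return self.interval.id

    @property
    def is_methylated(self) -> bool:
        return self.call in METHYLATED_CALLS


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------

def promoter_windows(
    genes: Sequence[GeneModel], window_width: int = 500
) -> list[GenomicInterval]:
    """Split each 2500-bp promoter into consecutive windows of
    ``window_width`` (500 bp -> five windows per gene).

    Window 1 is the most upstream in transcribed orientation, so minus-strand
    promoters are numbered right to left.  Windows are named
    ``<gene_id>:<index>``.
    """
    out = []
    for gene in genes:
        promoter = gene.promoter
        if promoter.length % window_width != 0:
            raise ValueError("window_width must divide the promoter length")
        n = promoter.length // window_width
        starts = range(promoter.start, promoter.end, window_width)
        ordered = list(starts) if gene.strand == "+" else list(starts)[::-1]
        for i, s in enumerate(ordered, start=1):
            out.append(
                GenomicInterval(gene.chrom, s, s + window_width, gene.strand,
                                name=f"{gene.gene_id}:{i}")
            )
    return out


def tile_genome(
    chrom_lengths: dict[str, int], width: int = 1000
) -> list[GenomicInterval]:
    """Non-overlapping exhaustive tiling; the last tile is truncated."""
    if width <= 0:
        raise ValueError("width must be positive")
    tiles = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for start in range(0, length, width):
            tiles.append(GenomicInterval(chrom, start, min(start + width, length)))
    return tiles


class CpGIndex:
    """Sorted CpG positions per chromosome with window counting."""

    def __init__(self, positions: dict[str, np.ndarray] | dict[str, Sequence[int]]):
        self.pos = {
            c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in positions.items()
        }

    def count_in(self, window: GenomicInterval) -> int:
        pos = self.pos.get(window.chrom)
        if pos is None:
            return 0
        lo = np.searchsorted(pos, window.start, side="left")
        hi = np.searchsorted(pos, window.end, side="left")
        return int(hi - lo)

    def in_window(self, window: GenomicInterval) -> np.ndarray:
        pos = self.pos.get(window.chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(pos, window.start, side="left")
        hi = np.searchsorted(pos, window.end, side="left")
        return pos[lo:hi]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def capture_rms(
    window: GenomicInterval,
    capture_track: BinnedTrack,
    cpgs: CpGIndex,
) -> MethylWindow:
    """Relative methylation score for a capture-assay window.

    rms = window RPKM / CpG count.  A window without CpGs gets ``no_data``
    (capture signal is uninterpretable where there is nothing to capture).
    """
    n_cpg = cpgs.count_in(window)
    count = capture_track.window_count(window)
    if n_cpg == 0:
        return MethylWindow(window, "capture", float("nan"), int(round(count)),
                            0, call=NO_DATA)
    rms = capture_track.window_rpkm(window) / n_cpg
    return MethylWindow(window, "capture", rms, int(round(count)), n_cpg)


def bisulfite_ams(
    window: GenomicInterval,
    sites: BisulfiteTable,
    min_coverage: int = 10,
) -> MethylWindow:
    """Absolute methylation signal: pooled sum(C)/sum(C+T) over the window.

    Coverage below ``min_coverage`` (summed over sites) yields ``no_data``.
    """
    c, t, n_sites = sites.window_counts(window)
    cov = c + t
    if cov < max(min_coverage, 1):  # the ratio is undefined at zero coverage
        return MethylWindow(window, "bisulfite", float("nan"), cov, n_sites,
                            call=NO_DATA)
    return MethylWindow(window, "bisulfite", c / cov, cov, n_sites)


# ---------------------------------------------------------------------------
# Testing and calling
# ---------------------------------------------------------------------------

def binomial_methylation_call(
    count_c: int, coverage: int, p0: float, alternative: str = "greater"
) -> float:
    """One-sided exact binomial tail: P(X >= C | n, p0) for 'greater'."""
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0, 1)")
    if not (0 <= count_c <= coverage):
        raise ValueError("count_c must be in [0, coverage]")
    if alternative == "greater":
        return float(stats.binom.sf(count_c - 1, coverage, p0))
    if alternative == "less":
        return float(stats.binom.cdf(count_c, coverage, p0))
    raise ValueError(f"unknown alternative {alternative!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_bisulfite_regions(
    windows: Sequence[GenomicInterval],
    sites: BisulfiteTable,
    min_coverage: int = 10,
    alpha: float = 0.01,
    p_methylated: float = 0.25,
    p_high: float = 0.75,
) -> list[MethylWindow]:
    """Score and call bisulfite windows.

    Two one-sided binomial test families are run over all windows with
    sufficient coverage — ratio > ``p_methylated`` and ratio > ``p_high`` —
    and BH-adjusted separately.  A window is *highly_methylated* when the
    high test passes at ``alpha``, else *methylated* when the low test
    passes, else *unmethylated*; windows below ``min_coverage`` are
    ``no_data``.
    """
    scored = [bisulfite_ams(w, sites, min_coverage) for w in windows]
    tested = [w for w in scored if w.call != NO_DATA]
    if tested:
        c = np.array([round(w.score * w.coverage) for w in tested], dtype=int)
        n = np.array([w.coverage for w in tested], dtype=int)
        p_low = stats.binom.sf(c - 1, n, p_methylated)
        p_hi = stats.binom.sf(c - 1, n, p_high)
        q_low = bh_adjust(p_low)
        q_hi = bh_adjust(p_hi)
        for w, pl, ph, ql, qh in zip(tested, p_low, p_hi, q_low, q_hi):
            w.p_value, w.q_value = float(pl), float(ql)
            w.p_value_high, w.q_value_high = float(ph), float(qh)
            if qh < alpha:
                w.call = HIGHLY_METHYLATED
            elif ql < alpha:
                w.call = METHYLATED
            else:
                w.call = UNMETHYLATED
    return scored


def call_capture_hmrs(
    capture: BinnedTrack,
    input_track: BinnedTrack,
    tiles: Sequence[GenomicInterval],
    alpha: float = 0.01,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
    cpgs: Optional[CpGIndex] = None,
) -> list[MethylWindow]:
    """Call highly methylated regions from a capture track against its input.

    Per tile, the capture count is tested against capture + input with an
    exact one-sided binomial whose null proportion is the capture library's
    share of the pooled depth; p-values are BH-adjusted across tiles.  The
    fold change is the depth-normalised ratio with ``pseudocount`` added to
    both counts.  A tile is *highly_methylated* iff q < ``alpha`` and
    fold > ``min_fold``; tiles with no reads in either library are
    ``no_data``.
    """
    if capture.bin_width != input_track.bin_width:
        raise ValueError("capture and input tracks must share the bin grid")
    if capture.library_size <= 0 or input_track.library_size <= 0:
        raise ValueError("both tracks need a recorded library size")
    share = capture.library_size / (capture.library_size + input_track.library_size)
    out = []
    cap_counts = np.empty(len(tiles), dtype=int)
    in_counts = np.empty(len(tiles), dtype=int)
    for i, tile in enumerate(tiles):
        cap_counts[i] = round(capture.window_count(tile))
        in_counts[i] = round(input_track.window_count(tile))
    total = cap_counts + in_counts
    tested = total > 0
    p = np.ones(len(tiles))
    p[tested] = stats.binom.sf(cap_counts[tested] - 1, total[tested], share)
    q = np.full(len(tiles), np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    folds = ((cap_counts + pseudocount) / capture.library_size) / (
        (in_counts + pseudocount) / input_track.library_size
    )
    for i, tile in enumerate(tiles):
        n_cpg = cpgs.count_in(tile) if cpgs is not None else 0
        if not tested[i]:
            out.append(
                MethylWindow(tile, "capture", float("nan"), 0, n_cpg, call=NO_DATA)
            )
            continue
        rpkm = capture.window_rpkm(tile)
        score = rpkm / n_cpg if n_cpg > 0 else rpkm
        call = (
            HIGHLY_METHYLATED
            if (q[i] < alpha and folds[i] > min_fold)
            else UNMETHYLATED
        )
        out.append(
            MethylWindow(
                tile, "capture", score, int(cap_counts[i]), n_cpg,
                p_value=float(p[i]), q_value=float(q[i]),
                call=call, fold=float(folds[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Comparison and summaries
# ---------------------------------------------------------------------------

def cross_platform_correlation(
    capture_windows: Sequence[MethylWindow],
    bisulfite_windows: Sequence[MethylWindow],
    include_no_data: bool = False,
) -> tuple[float, int]:
    """Pearson correlation of per-window scores across the two assays.

    Windows are paired by id; pairs where either assay has ``no_data`` are
    dropped (default) or scored as 0 when ``include_no_data`` is set.
    """
    b_by_id = {w.id: w for w in bisulfite_windows}
    xs, ys = [], []
    for cw in capture_windows:
        bw = b_by_id.get(cw.id)
        if bw is None:
            continue
        if cw.call == NO_DATA or bw.call == NO_DATA:
            if not include_no_data:
                continue
            xs.append(0.0 if cw.call == NO_DATA else cw.score)
            ys.append(0.0 if bw.call == NO_DATA else bw.score)
        else:
            xs.append(cw.score)
            ys.append(bw.score)
    if len(xs) < 3:
        raise InsufficientDataError(
            f"need >= 3 paired windows with data, got {len(xs)}"
        )
    x, y = np.asarray(xs), np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a score vector is constant")
    r = float(stats.pearsonr(x, y).statistic)
    return r, len(xs)


def promoter_gene_calls(windows: Sequence[MethylWindow]) -> dict[str, bool]:
    """Gene-level promoter methylation: True when any ``gene:index`` window
    is called methylated or higher."""
    calls: dict[str, bool] = {}
    for w in windows:
        name = w.interval.name
        if name is None or ":" not in name:
            raise ValueError(f"window {w.id} lacks a gene:index name")
        gene = name.rsplit(":", 1)[0]
        calls[gene] = calls.get(gene, False) or w.is_methylated
    return calls


@dataclass
class PromoterComparison:
    a_specific: set[str]
    b_specific: set[str]
    shared: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "a_specific": len(self.a_specific),
            "b_specific": len(self.b_specific),
            "shared": len(self.shared),
        }


def compare_promoter_calls(
    calls_a: dict[str, bool], calls_b: dict[str, bool]
) -> PromoterComparison:
    """Partition genes methylated in either condition by agreement."""
    if set(calls_a) != set(calls_b):
        raise ValueError("the two call sets must cover the same genes")
    a = {g for g, m in calls_a.items() if m}
    b = {g for g, m in calls_b.items() if m}
    return PromoterComparison(
        a_specific=a - b, b_specific=b - a, shared=a & b
    )


def gene_body_calls(
    genes: Sequence[GeneModel],
    tile_calls: Sequence[MethylWindow],
    interior_margin: Optional[int] = None,
) -> dict[str, bool]:
    """Gene-level body methylation from called tiles.

    With ``interior_margin=None`` a gene is body-methylated when any called
    tile overlaps the gene body.  With a margin, only tiles lying fully
    inside the promoter-trimmed body interior count, which prevents
    promoter methylation from bleeding into the body call; genes whose
    interior is too short to hold a tile are reported unmethylated.
    """
    called = PeakSet(
        mark="methylated", cell_type="",
        intervals=[w.interval for w in tile_calls if w.is_methylated],
    )
    out = {}
    for g in genes:
        if interior_margin is None:
            out[g.gene_id] = called.any_overlap(g.body)
            continue
        interior = g.body_interior(interior_margin)
        if interior is None:
            out[g.gene_id] = False
            continue
        hits = called.overlapping(interior)
        out[g.gene_id] = any(
            h.start >= interior.start and h.end <= interior.end for h in hits
        )
    return out


PROMOTER_METHYLATED = "promoter_methylated"
BODY_ONLY = "body_only"
HYPOMETHYLATED = "hypomethylated"


def categorize_genes_by_methylation(
    promoter_calls: dict[str, bool], body_calls: dict[str, bool]
) -> tuple[dict[str, str], float]:
    """Three-way gene partition by methylation location.

    Promoter methylation takes precedence over body-only; genes methylated
    nowhere are hypomethylated.  Also returns the fraction of
    promoter-methylated genes whose body is methylated too (nan when no gene
    has a methylated promoter).
    """
    if set(promoter_calls) != set(body_calls):
        raise ValueError("promoter and body call sets must cover the same genes")
    categories = {}
    n_prom = n_both = 0
    for gene, prom in promoter_calls.items():
        body = body_calls[gene]
        if prom:
            categories[gene] = PROMOTER_METHYLATED
            n_prom += 1
            n_both += body
        elif body:
            categories[gene] = BODY_ONLY
        else:
            categories[gene] = HYPOMETHYLATED
    frac = n_both / n_prom if n_prom else float("nan")
    return categories, frac


def annotation_methylation_frequency(
    annotations: PeakSet,
    calls: Sequence[MethylWindow],
    require_cpg_island_overlap: bool = False,
    cpg_islands: Optional[PeakSet] = None,
) -> dict[str, tuple[Optional[float], int]]:
    """Per-family fraction of annotation loci overlapping a methylated window.

    Families come from the interval ``name`` field (e.g. TE family labels).
    With ``require_cpg_island_overlap`` the denominator is restricted to loci
    overlapping a CpG island.  Empty families report ``(None, 0)`` rather
    than a zero frequency.
    """
    if require_cpg_island_overlap and cpg_islands is None:
        raise ValueError("cpg_islands required when restricting to island loci")
    called = PeakSet(
        mark="methylated", cell_type="",
        intervals=[w.interval for w in calls if w.is_methylated],
    )
    loci_by_family: dict[str, list[GenomicInterval]] = {}
    for iv in annotations:
        loci_by_family.setdefault(iv.name or "unnamed", []).append(iv)
    out = {}
    for family, loci in sorted(loci_by_family.items()):
        if require_cpg_island_overlap:
            loci = [iv for iv in loci if cpg_islands.any_overlap(iv)]
        if not loci:
            out[family] = (None, 0)
            continue
        n_meth = sum(called.any_overlap(iv) for iv in loci)
        out[family] = (n_meth / len(loci), len(loci))
    return out


def locus_methylation_status(
    annotations: PeakSet, calls_by_assay: dict[str, Sequence[MethylWindow]]
) -> pd.DataFrame:
    """Per-locus methylation status across assays (e.g. imprinted DMRs).

    Rows are annotation loci, one boolean column per assay label.
    """
    rows = []
    called_sets = {
        label: PeakSet(
            mark="methylated", cell_type="",
            intervals=[w.interval for w in calls if w.is_methylated],
        )
        for label, calls in calls_by_assay.items()
    }
    for iv in annotations:
        row = {"locus": iv.id, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
        for label, called in called_sets.items():
            row[label] = bool(called.any_overlap(iv))
        rows.append(row)
    return pd.DataFrame(rows)


def write_methyl_windows(windows: Sequence[MethylWindow], path) -> None:
    """Per-window TSV: interval, assay, score, coverage, CpGs, p, q, call."""
    def fmt(x):
        return "" if x is None else f"{x:.6g}"

    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tassay\tscore\tcoverage\tcpg_count"
                 "\tp_value\tq_value\tfold\tcall\n")
        for w in windows:
            iv = w.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{w.assay}\t"
                f"{w.score:.6g}\t{w.coverage}\t{w.cpg_count}\t{fmt(w.p_value)}\t"
                f"{fmt(w.q_value)}\t{fmt(w.fold)}\t{w.call}\n"
            )
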