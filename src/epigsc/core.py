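"""Coordinate conventions, interval containers and flat-file readers/writers.

Everything downstream (peaks, promoter windows, methylation tiles, TE and
CpG-island annotations) is built on :class:`GenomicInterval`, which uses the
BED convention throughout: 0-based, half-open ``[start, end)``.  Inputs that
arrive 1-based (the bisulfite position column) are converted at the reader
boundary so that no other module ever has to think about the offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

#: promoter extent relative to the TSS, in transcribed orientation
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500


class BedParseError(ValueError):
    """Raised when a BED/TSV line cannot be parsed; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).  ``name`` and
    ``score`` are optional BED-style annotations.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floored — the anchor used for signal windows and
        TSS-distance calculations."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    @property
    def id(self) -> str:
        """Stable row identifier: the name if set, else ``chrom:start-end``."""
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share at least one base (half-open)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored by its strand-aware transcription start site.

    The promoter is the window from 2 kb upstream to 500 bp downstream of
    the TSS in transcribed orientation, so it is always exactly 2500 bp.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.body_start < self.body_end:
            raise ValueError(f"gene {self.gene_id}: body_start must be < body_end")
        if not (self.body_start <= self.tss <= self.body_end):
            raise ValueError(f"gene {self.gene_id}: TSS outside gene body")

    @property
    def promoter(self) -> GenomicInterval:
        if self.strand == "+":
            start = self.tss - PROMOTER_UPSTREAM
            end = self.tss + PROMOTER_DOWNSTREAM
        else:
            # reflected: upstream is increasing coordinates
            start = self.tss - PROMOTER_DOWNSTREAM + 1
            end = self.tss + PROMOTER_UPSTREAM + 1
        return GenomicInterval(self.chrom, start, end, self.strand,
                               name=self.gene_id)

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.body_start, self.body_end,
                               self.strand, name=self.gene_id)

    def body_interior(self, margin: int = 1000) -> Optional[GenomicInterval]:
        """The gene body clear of the promoter region: the body trimmed by
        ``margin`` downstream of the TSS, or None when shorter than 1 kb.
        Useful to measure gene-body methylation without promoter bleed-in."""
        if self.strand == "+":
            start, end = self.tss + margin, self.body_end
        else:
            start, end = self.body_start, self.tss - margin
        if end - start < 1000:
            return None
        return GenomicInterval(self.chrom, start, end, self.strand,
                               name=self.gene_id)


@dataclass
class PeakSet:
    """A sorted collection of intervals for one assay in one cell type."""

    mark: str
    cell_type: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    _trees: Optional[dict] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._trees = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def _build_trees(self) -> dict:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, iv
                )
            self._trees = trees
        return self._trees

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        tree = self._build_trees().get(query.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(query.start, query.end)]
        return sorted(hits, key=lambda iv: (iv.start, iv.end))

    def any_overlap(self, query: GenomicInterval) -> bool:
        tree = self._build_trees().get(query.chrom)
        return bool(tree and tree.overlaps(query.start, query.end))


class TSSIndex:
    """Fast nearest-TSS queries over a gene set, per chromosome."""

    def __init__(self, genes: Sequence[GeneModel]):
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self._pos: dict[str, np.ndarray] = {}
        self._genes: dict[str, list[GeneModel]] = {}
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._pos[chrom] = np.array([g.tss for g in gs], dtype=np.int64)
            self._genes[chrom] = gs

    def nearest(self, chrom: str, pos: int) -> Optional[tuple[GeneModel, int]]:
        """Return ``(gene, signed_distance)`` for the nearest TSS, or None if
        the chromosome carries no gene.

        The distance is signed in transcribed orientation: negative means the
        query lies upstream of the gene, positive downstream.  Ties on
        absolute distance are broken by lexicographically smaller gene id.
        """
        tss = self._pos.get(chrom)
        if tss is None or len(tss) == 0:
            return None
        i = int(np.searchsorted(tss, pos))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                d = abs(pos - int(tss[j]))
                if best is None or d < best:
                    best = d
        # all genes at the minimal absolute distance; pick smallest id
        lo = int(np.searchsorted(tss, pos - best, side="left"))
        hi = int(np.searchsorted(tss, pos + best, side="right"))
        candidates = [
            g for g in self._genes[chrom][lo:hi] if abs(pos - g.tss) == best
        ]
        gene = min(candidates, key=lambda g: g.gene_id)
        signed = (pos - gene.tss) if gene.strand == "+" else (gene.tss - pos)
        return gene, signed


def nearest_tss_distance(
    peak: GenomicInterval,
    genes: Sequence[GeneModel] | TSSIndex,
    signed: bool = True,
) -> int:
    """Distance from the peak center to the nearest TSS.

    Signed by default (upstream negative, downstream positive in gene
    orientation); pass ``signed=False`` for the absolute distance.
    """
    index = genes if isinstance(genes, TSSIndex) else TSSIndex(genes)
    hit = index.nearest(peak.chrom, peak.center)
    if hit is None:
        raise ValueError(f"no gene on chromosome {peak.chrom}")
    _, dist = hit
    return dist if signed else abs(dist)


def nearest_gene_within(
    peak: GenomicInterval,
    genes: Sequence[GeneModel] | TSSIndex,
    max_dist: int = 200_000,
) -> Optional[str]:
    """Single nearest gene (by TSS) within ``max_dist`` of the peak center."""
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    index = genes if isinstance(genes, TSSIndex) else TSSIndex(genes)
    hit = index.nearest(peak.chrom, peak.center)
    if hit is None:
        return None
    gene, dist = hit
    return gene.gene_id if abs(dist) <= max_dist else None


# ---------------------------------------------------------------------------
# Flat-file I/O
# ---------------------------------------------------------------------------

def read_bed(path, mark: str = "", cell_type: str = "") -> PeakSet:
    """Read a BED3/BED6 file into a :class:`PeakSet` (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(path, lineno, "expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(path, lineno, f"non-integer coordinate: {exc}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(path, lineno, f"non-numeric score: {exc}")
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand, name, score)
                )
            except ValueError as exc:
                raise BedParseError(path, lineno, str(exc))
    return PeakSet(mark=mark, cell_type=cell_type, intervals=intervals)


def write_bed(intervals: Iterable[GenomicInterval] | PeakSet, path) -> None:
    """Write intervals as BED6 (name/score/strand filled with defaults)."""
    if isinstance(intervals, PeakSet):
        intervals = intervals.intervals
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


GENE_TSV_HEADER = ["gene_id", "chrom", "strand", "tss", "body_start", "body_end"]


def read_gene_models(path) -> list[GeneModel]:
    """Read the tab-separated gene model table (header required)."""
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GENE_TSV_HEADER:
            raise BedParseError(path, 1, f"unexpected header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 6:
                raise BedParseError(path, lineno, "expected 6 columns")
            try:
                genes.append(
                    GeneModel(f[0], f[1], f[2], int(f[3]), int(f[4]), int(f[5]))
                )
            except ValueError as exc:
                raise BedParseError(path, lineno, str(exc))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TSV_HEADER) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t"
                f"{g.body_start}\t{g.body_end}\n"
            )
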