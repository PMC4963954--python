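"""Binned coverage tracks and the signal-clustering pipeline.

Sequencing coverage is summarised in fixed-width bins (50 bp by default) and
normalised to reads per kilobase per million mapped reads (RPKM).  For
clustering, tracks are smoothed with a rectangular mean kernel and
square-root transformed to damp noise and outliers, then a signal matrix is
extracted in a fixed window around each region center and partitioned with
K-means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
from sklearn.cluster import kmeans_plusplus

from .core import GenomicInterval, PeakSet

RAW = "raw_counts"
RPKM = "rpkm"


def _rpkm_factor(bin_width: int, library_size: int) -> float:
    """counts -> RPKM conversion factor for one bin.

    An empty library maps every (necessarily zero) count to zero.
    """
    if library_size == 0:
        return 0.0
    return 1.0 / ((bin_width / 1000.0) * (library_size / 1e6))


@dataclass
class BinnedTrack:
    """Genome-wide fixed-width binned signal for one assay in one cell type.

    ``data`` maps chromosome -> dense array of length ``ceil(len/bin_width)``
    holding values in the units named by ``normalization`` (raw counts or
    RPKM).  ``library_size`` is the total number of reads binned, which makes
    the two unit systems interconvertible.
    """

    bin_width: int
    chrom_lengths: dict[str, int]
    data: dict[str, np.ndarray]
    normalization: str = RAW
    library_size: int = 0

    def __post_init__(self):
        if self.normalization not in (RAW, RPKM):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for chrom, length in self.chrom_lengths.items():
            expected = math.ceil(length / self.bin_width)
            if len(self.data[chrom]) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {len(self.data[chrom])}"
                )

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    def counts(self, chrom: str) -> np.ndarray:
        """Per-bin raw read counts (back-converted if stored as RPKM)."""
        v = self.data[chrom]
        if self.normalization == RAW:
            return v
        f = _rpkm_factor(self.bin_width, self.library_size)
        return v / f if f else np.zeros_like(v)

    def rpkm(self, chrom: str) -> np.ndarray:
        v = self.data[chrom]
        if self.normalization == RPKM:
            return v
        return v * _rpkm_factor(self.bin_width, self.library_size)

    def to_rpkm(self) -> "BinnedTrack":
        if self.normalization == RPKM:
            return self
        f = _rpkm_factor(self.bin_width, self.library_size)
        return BinnedTrack(
            self.bin_width,
            dict(self.chrom_lengths),
            {c: v.astype(float) * f for c, v in self.data.items()},
            RPKM,
            self.library_size,
        )

    def window_count(self, window: GenomicInterval) -> float:
        """Raw read count attributed to a window, prorating partial bins."""
        counts = self.counts(window.chrom)
        bw = self.bin_width
        n = len(counts)
        start = max(window.start, 0)
        end = min(window.end, n * bw)
        if start >= end:
            return 0.0
        b0, b1 = start // bw, (end - 1) // bw
        if b0 == b1:
            return float(counts[b0]) * (end - start) / bw
        total = float(counts[b0]) * ((b0 + 1) * bw - start) / bw
        total += float(counts[b1]) * (end - b1 * bw) / bw
        if b1 - b0 > 1:
            total += float(counts[b0 + 1:b1].sum())
        return total

    def window_rpkm(self, window: GenomicInterval) -> float:
        count = self.window_count(window)
        if self.library_size == 0:
            return 0.0
        return count / ((window.length / 1000.0) * (self.library_size / 1e6))


def bin_and_normalize(
    read_positions: Iterable[tuple[str, int]],
    chrom_lengths: dict[str, int],
    bin_width: int = 50,
    mode: str = RPKM,
) -> BinnedTrack:
    """Bin read positions (5' ends) into fixed-width bins and normalise.

    RPKM for a bin with ``c`` reads is ``c / (bin_kb * library_millions)``
    where the library size is the total number of input positions.  Raises on
    positions outside the stated chromosome bounds.
    """
    per_chrom: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    total = 0
    for chrom, pos in read_positions:
        if chrom not in chrom_lengths:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        if not (0 <= pos < chrom_lengths[chrom]):
            raise ValueError(f"read position {chrom}:{pos} out of bounds")
        per_chrom[chrom].append(pos)
        total += 1
    data = {}
    for chrom, length in chrom_lengths.items():
        nbins = math.ceil(length / bin_width)
        pos = np.asarray(per_chrom[chrom], dtype=np.int64)
        counts = np.bincount(pos // bin_width, minlength=nbins).astype(float)
        data[chrom] = counts
    track = BinnedTrack(bin_width, dict(chrom_lengths), data, RAW, total)
    return track.to_rpkm() if mode == RPKM else track


def track_from_counts(
    counts: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    bin_width: int = 50,
    mode: str = RPKM,
) -> BinnedTrack:
    """Wrap precomputed per-bin counts; library size is their sum."""
    total = int(sum(v.sum() for v in counts.values()))
    track = BinnedTrack(
        bin_width, dict(chrom_lengths),
        {c: np.asarray(v, dtype=float) for c, v in counts.items()},
        RAW, total,
    )
    return track.to_rpkm() if mode == RPKM else track


# ---------------------------------------------------------------------------
# Smoothing and transformation
# ---------------------------------------------------------------------------

def _blur_1d(values: np.ndarray, half_width: int) -> np.ndarray:
    n = len(values)
    if half_width == 0 or n == 0:
        return values.astype(float).copy()
    cs = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_width, 0)
    hi = np.minimum(idx + half_width + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def blur_rectangular(obj, half_width_bins: int):
    """Rectangular (boxcar) mean filter with truncated edges.

    Each value becomes the mean over ``[i - w, i + w]`` restricted to valid
    indices, so constant signal is preserved exactly at the edges.  Accepts a
    1-D array, a 2-D array (filtered along rows), a :class:`BinnedTrack` or a
    :class:`SignalMatrix` and returns the same shape/type.
    """
    if half_width_bins < 0:
        raise ValueError("half_width_bins must be >= 0")
    if isinstance(obj, BinnedTrack):
        return BinnedTrack(
            obj.bin_width, dict(obj.chrom_lengths),
            {c: _blur_1d(v, half_width_bins) for c, v in obj.data.items()},
            obj.normalization, obj.library_size,
        )
    if isinstance(obj, SignalMatrix):
        return SignalMatrix(
            obj.row_ids,
            np.vstack([_blur_1d(r, half_width_bins) for r in obj.values])
            if len(obj.values) else obj.values.copy(),
            obj.bin_width, obj.flank,
        )
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 1:
        return _blur_1d(arr, half_width_bins)
    if arr.ndim == 2:
        return np.vstack([_blur_1d(r, half_width_bins) for r in arr])
    raise ValueError("expected 1-D or 2-D input")


def sqrt_transform(obj):
    """Elementwise square root; rejects negative input."""
    if isinstance(obj, BinnedTrack):
        for v in obj.data.values():
            if np.any(v < 0):
                raise ValueError("negative signal value")
        return BinnedTrack(
            obj.bin_width, dict(obj.chrom_lengths),
            {c: np.sqrt(v) for c, v in obj.data.items()},
            obj.normalization, obj.library_size,
        )
    if isinstance(obj, SignalMatrix):
        if np.any(obj.values < 0):
            raise ValueError("negative signal value")
        return SignalMatrix(obj.row_ids, np.sqrt(obj.values), obj.bin_width, obj.flank)
    arr = np.asarray(obj, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative signal value")
    return np.sqrt(arr)


# ---------------------------------------------------------------------------
# Region-centred signal matrices
# ---------------------------------------------------------------------------

@dataclass
class SignalMatrix:
    """Signal in a fixed window around each region center: one row per
    region, one column per bin spanning ``[center - flank, center + flank)``."""

    row_ids: list[str]
    values: np.ndarray  # shape (n_regions, 2 * flank / bin_width)
    bin_width: int
    flank: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row id count does not match matrix rows")

    @property
    def n_cols(self) -> int:
        return 2 * self.flank // self.bin_width


def extract_signal_matrix(
    track: BinnedTrack,
    regions: Union[PeakSet, Sequence[GenomicInterval]],
    flank: int = 5000,
) -> SignalMatrix:
    """One row per region, columns covering ``[center - flank, center + flank)``.

    Columns that fall outside the chromosome are zero-filled so all rows have
    identical width.
    """
    if flank % track.bin_width != 0:
        raise ValueError("flank must be a multiple of the bin width")
    if isinstance(regions, PeakSet):
        regions = regions.intervals
    half = flank // track.bin_width
    ncols = 2 * half
    rows, ids = [], []
    for iv in regions:
        values = track.data[iv.chrom]
        c_bin = iv.center // track.bin_width
        lo, hi = c_bin - half, c_bin + half
        row = np.zeros(ncols)
        src_lo, src_hi = max(lo, 0), min(hi, len(values))
        if src_lo < src_hi:
            row[src_lo - lo:src_hi - lo] = values[src_lo:src_hi]
        rows.append(row)
        ids.append(iv.id)
    values = np.vstack(rows) if rows else np.zeros((0, ncols))
    return SignalMatrix(ids, values, track.bin_width, flank)


# ---------------------------------------------------------------------------
# K-means
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """K-means partition of signal-matrix rows.

    Labels run 1..k and are renumbered by descending centroid mean so the
    numbering is reproducible across runs (raw K-means label order is
    arbitrary).  ``inertia_trace`` records the within-cluster sum of squares
    after every Lloyd iteration; it is non-increasing by construction.
    """

    k: int
    row_ids: list[str]
    labels: np.ndarray  # 1-based class per row
    centroids: np.ndarray  # row i = centroid of class i+1
    seed: int
    inertia: float
    inertia_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def assignments(self) -> dict[str, int]:
        return {rid: int(lab) for rid, lab in zip(self.row_ids, self.labels)}

    def members(self, label: int) -> list[str]:
        return [rid for rid, lab in zip(self.row_ids, self.labels) if lab == label]


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float):
    trace = []
    labels = None
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(X)), labels].sum())
        trace.append(inertia)
        new_centers = centers.copy()
        for j in range(len(centers)):
            mask = labels == j
            if mask.any():
                new_centers[j] = X[mask].mean(axis=0)
            else:
                # re-seed an empty cluster at the worst-fit point
                far = int(d2[np.arange(len(X)), labels].argmax())
                new_centers[j] = X[far]
        shift = float(np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max())
        centers = new_centers
        if shift < tol:
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(X)), labels].sum())
    trace.append(inertia)
    return labels, centers, inertia, trace, it


def kmeans_cluster(
    matrices: Sequence[SignalMatrix],
    k: int,
    seed: int,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterResult:
    """Lloyd's K-means over column-concatenated signal matrices.

    All matrices must carry identical row ids (one matrix per mark/cell-type
    combination over the same regions).  Initialisation is seeded k-means++;
    iteration stops when no centroid moves more than ``tol`` or after
    ``max_iter`` rounds.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not matrices:
        raise ValueError("need at least one signal matrix")
    row_ids = matrices[0].row_ids
    for m in matrices[1:]:
        if m.row_ids != row_ids:
            raise ValueError("signal matrices must share identical row ids")
    X = np.hstack([m.values for m in matrices])
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    labels, centers, inertia, trace, n_iter = _lloyd(X, centers, max_iter, tol)
    # stable numbering: class 1 has the highest mean signal
    order = np.argsort(-centers.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return ClusterResult(
        k=k,
        row_ids=list(row_ids),
        labels=relabel[labels],
        centroids=centers[order],
        seed=seed,
        inertia=inertia,
        inertia_trace=trace,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a fixed-step bedGraph (one line per bin, zeros included).

    A comment header records bin width, normalization and library size so the
    file round-trips through :func:`read_bedgraph` without loss.
    """
    with open(path, "w") as fh:
        fh.write(f"# bin_width={track.bin_width} normalization={track.normalization} "
                 f"library_size={track.library_size}\n")
        for chrom in track.chroms:
            length = track.chrom_lengths[chrom]
            values = track.data[chrom]
            bw = track.bin_width
            for i, v in enumerate(values):
                end = min((i + 1) * bw, length)
                fh.write(f"{chrom}\t{i * bw}\t{end}\t{v:.6g}\n")


def read_bedgraph(path) -> BinnedTrack:
    header: dict[str, str] = {}
    data: dict[str, list[float]] = {}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, val = token.split("=", 1)
                        header[key] = val
                continue
            if not line or line.startswith("track"):
                continue
            chrom, start, end, value = line.split("\t")
            data.setdefault(chrom, []).append(float(value))
            lengths[chrom] = max(lengths.get(chrom, 0), int(end))
    bw = int(header.get("bin_width", 50))
    return BinnedTrack(
        bw,
        lengths,
        {c: np.array(v) for c, v in data.items()},
        header.get("normalization", RPKM),
        int(header.get("library_size", 0)),
    )
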