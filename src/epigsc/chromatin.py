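"""Rule-based chromatin-state classification from peak sets.

Enhancers are distal H3K4me1 peaks, split into *active* (co-occupied by
H3K27ac) and *poised* (H3K4me1 alone).  Bivalent promoters carry both the
activating H3K4me3 and the repressive H3K27me3 mark.  Presence of a mark is
operationalised as interval overlap between the called peak and the region
of interest (>= 1 bp by default; a minimum overlap fraction can be
required).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    TSSIndex,
    nearest_gene_within,
)
from .tracks import ClusterResult

ACTIVE = "active"
POISED = "poised"


@dataclass(frozen=True)
class EnhancerCall:
    interval: GenomicInterval
    state: str  # active | poised
    cell_type: str
    nearest_gene: Optional[str]
    tss_distance: int  # signed, transcribed orientation of the nearest gene


@dataclass(frozen=True)
class PromoterState:
    gene_id: str
    marks_present: frozenset
    bivalent: bool


def _overlap_fraction(peak: GenomicInterval, hits: list[GenomicInterval]) -> float:
    if not hits:
        return 0.0
    covered = 0
    for h in hits:
        covered += min(peak.end, h.end) - max(peak.start, h.start)
    return min(covered / peak.length, 1.0)


def classify_enhancers(
    k4me1: PeakSet,
    k27ac: PeakSet,
    genes: Sequence[GeneModel],
    exclude_promoter_proximal: bool = True,
    proximal_dist: int = 2000,
    max_gene_dist: int = 200_000,
    min_overlap_fraction: float = 0.0,
) -> list[EnhancerCall]:
    """Classify H3K4me1 peaks into active/poised enhancers.

    Candidates are the H3K4me1 peaks, optionally excluding those whose
    center lies within ``proximal_dist`` of any TSS (promoter-proximal
    H3K4me1 reflects promoter chromatin rather than enhancers).  A candidate
    is *active* when an H3K27ac peak overlaps it (by at least
    ``min_overlap_fraction`` of the candidate, default any overlap), else
    *poised*.  Each call carries the signed distance to its nearest TSS and
    the single nearest gene within ``max_gene_dist``.
    """
    index = TSSIndex(genes)
    calls = []
    for peak in k4me1:
        hit = index.nearest(peak.chrom, peak.center)
        if hit is None:
            continue
        gene, signed = hit
        if exclude_promoter_proximal and abs(signed) <= proximal_dist:
            continue
        overlapping = k27ac.overlapping(peak)
        if min_overlap_fraction > 0:
            is_active = _overlap_fraction(peak, overlapping) >= min_overlap_fraction
        else:
            is_active = bool(overlapping)
        calls.append(
            EnhancerCall(
                interval=peak,
                state=ACTIVE if is_active else POISED,
                cell_type=k4me1.cell_type,
                nearest_gene=nearest_gene_within(peak, index, max_gene_dist),
                tss_distance=signed,
            )
        )
    return calls


def enhancer_class_sets(
    cluster: ClusterResult, regions: PeakSet
) -> dict[int, PeakSet]:
    """Partition clustered enhancer regions into one PeakSet per class.

    ``regions`` must be the set the cluster rows were extracted from (matched
    by region id); classes may be empty if K-means left a centroid without
    members.
    """
    by_id = {iv.id: iv for iv in regions}
    if set(cluster.row_ids) != set(by_id):
        raise ValueError("cluster row ids do not match the supplied regions")
    out = {}
    for label in range(1, cluster.k + 1):
        members = [by_id[rid] for rid in cluster.members(label)]
        out[label] = PeakSet(
            mark=regions.mark, cell_type=regions.cell_type, intervals=members
        )
    return out


def call_bivalent_promoters(
    k4me3: PeakSet,
    k27me3: PeakSet,
    genes: Sequence[GeneModel],
) -> tuple[list[PromoterState], int]:
    """Per-gene promoter mark presence and the bivalent promoter count.

    A mark is present when any peak of that mark overlaps the gene's
    promoter; a promoter is bivalent when both H3K4me3 and H3K27me3 are
    present.
    """
    states = []
    n_bivalent = 0
    for gene in genes:
        promoter = gene.promoter
        marks = set()
        if k4me3.any_overlap(promoter):
            marks.add("H3K4me3")
        if k27me3.any_overlap(promoter):
            marks.add("H3K27me3")
        bivalent = marks == {"H3K4me3", "H3K27me3"}
        n_bivalent += bivalent
        states.append(PromoterState(gene.gene_id, frozenset(marks), bivalent))
    return states, n_bivalent


def peak_promoter_fraction(peaks: PeakSet, genes: Sequence[GeneModel]) -> float:
    """Fraction of peaks overlapping any gene promoter."""
    if len(peaks) == 0:
        raise ValueError("fraction undefined for an empty peak set")
    promoters = PeakSet(
        mark="promoter", cell_type="", intervals=[g.promoter for g in genes]
    )
    n_hit = sum(promoters.any_overlap(p) for p in peaks)
    return n_hit / len(peaks)


def tss_distance_histogram(
    calls: Sequence[EnhancerCall], breaks: Sequence[int]
) -> np.ndarray:
    """Histogram of signed TSS distances over ``breaks``.

    Returns ``len(breaks) + 1`` counts: an open-ended bin below the first
    break, the half-open bins ``[b_i, b_{i+1})``, and an open-ended bin at or
    above the last break.  The counts always sum to the number of calls.
    """
    breaks = list(breaks)
    if any(b >= c for b, c in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    edges = np.array([-np.inf] + breaks + [np.inf])
    dists = np.array([c.tss_distance for c in calls], dtype=float)
    counts, _ = np.histogram(dists, bins=edges)
    return counts
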