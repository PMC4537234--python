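"""Peak-to-gene assignment by TSS distance.

Peaks are reduced to an anchor point (narrowPeak summit when present,
else the interval midpoint), assigned to the nearest annotated TSS on
the same chromosome, and classified into four distance bins:
promoter (<= 1 kb), proximal (1-10 kb), distal (10-100 kb) and gene
desert (> 100 kb).  Distances are unsigned — the bins are symmetric
around the TSS.  A gene is "bound" when at least one peak anchor lies
within a window (default 200 kb, inclusive) of its TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .core import GeneRecord, GeneSet, GenomicInterval, RegionSet, ValidationError

CATEGORIES = ("promoter", "proximal_1_10kb", "distal_10_100kb", "gene_desert")

PROMOTER_BP = 1_000
PROXIMAL_BP = 10_000
DISTAL_BP = 100_000

AnchorMode = Literal["summit_or_midpoint", "midpoint"]


@dataclass(frozen=True)
class PeakAnnotation:
    region_id: str
    nearest_gene: str
    distance_bp: int
    category: str


def peak_anchor(interval: GenomicInterval, mode: AnchorMode = "summit_or_midpoint") -> int:
    """Anchor coordinate: the absolute summit when present (and requested),
    else ``floor((start + end) / 2)``."""
    if mode == "summit_or_midpoint" and interval.summit is not None:
        return interval.summit
    return (interval.start + interval.end) // 2


def classify_location(distance_bp: int) -> str:
    if distance_bp < 0:
        raise ValidationError(f"distance must be >= 0, got {distance_bp}")
    if distance_bp <= PROMOTER_BP:
        return "promoter"
    if distance_bp <= PROXIMAL_BP:
        return "proximal_1_10kb"
    if distance_bp <= DISTAL_BP:
        return "distal_10_100kb"
    return "gene_desert"


class _TssIndex:
    """Per-chromosome sorted TSS arrays with lexicographic tie-breaking."""

    def __init__(self, genes: Iterable[GeneRecord]):
        by_chrom: dict[str, list[GeneRecord]] = {}
        self.genes = list(genes)
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self._index: dict[str, tuple[np.ndarray, list[str]]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda g: (g.tss, g.gene_id))
            tss = np.array([g.tss for g in recs], dtype=np.int64)
            ids = [g.gene_id for g in recs]
            self._index[chrom] = (tss, ids)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def nearest(self, chrom: str, anchor: int) -> tuple[str, int] | None:
        """(gene_id, unsigned distance); ties -> lexicographically smallest id."""
        entry = self._index.get(chrom)
        if entry is None:
            return None
        tss, ids = entry
        pos = int(np.searchsorted(tss, anchor))
        best = None
        for j in (pos - 1, pos):
            if 0 <= j < len(tss):
                d = abs(int(tss[j]) - anchor)
                if best is None or d < best:
                    best = d
        assert best is not None
        candidates: list[str] = []
        for value in {anchor - best, anchor + best}:
            lo = int(np.searchsorted(tss, value, side="left"))
            hi = int(np.searchsorted(tss, value, side="right"))
            candidates.extend(ids[lo:hi])
        return min(candidates), best


def nearest_tss(
    interval: GenomicInterval,
    genes: Sequence[GeneRecord],
    anchor: AnchorMode = "summit_or_midpoint",
) -> tuple[str, int] | None:
    """Nearest same-chromosome TSS to the peak anchor, or None when the
    chromosome carries no annotated gene (the peak is then unassigned)."""
    return _TssIndex(genes).nearest(interval.chrom, peak_anchor(interval, anchor))


def annotate_peaks(
    rs: RegionSet,
    genes: Sequence[GeneRecord],
    anchor: AnchorMode = "summit_or_midpoint",
) -> tuple[list[PeakAnnotation], list[str]]:
    """Annotate every peak; returns (annotations, unassigned region_ids)."""
    index = _TssIndex(genes)
    annotations: list[PeakAnnotation] = []
    unassigned: list[str] = []
    for rid, iv in zip(rs.region_ids, rs.intervals):
        hit = index.nearest(iv.chrom, peak_anchor(iv, anchor))
        if hit is None:
            unassigned.append(rid)
        else:
            gene_id, d = hit
            annotations.append(PeakAnnotation(rid, gene_id, d, classify_location(d)))
    return annotations, unassigned


@dataclass(frozen=True)
class LocationDistribution:
    fractions: dict[str, float]
    n_assigned: int
    n_unassigned: int
    fraction_within_100kb: float
    fraction_within_200kb: float


def location_distribution(
    rs: RegionSet,
    genes: Sequence[GeneRecord],
    anchor: AnchorMode = "summit_or_midpoint",
) -> LocationDistribution:
    """Fraction of assignable peaks per distance category (sums to 1),
    plus the cumulative fractions within 100 kb and 200 kb of a TSS."""
    if len(rs) == 0:
        raise ValidationError("location_distribution of an empty RegionSet")
    annotations, unassigned = annotate_peaks(rs, genes, anchor)
    if not annotations:
        raise ValidationError("no peak could be assigned to any gene")
    n = len(annotations)
    counts = {c: 0 for c in CATEGORIES}
    within_100 = within_200 = 0
    for a in annotations:
        counts[a.category] += 1
        if a.distance_bp <= 100_000:
            within_100 += 1
        if a.distance_bp <= 200_000:
            within_200 += 1
    return LocationDistribution(
        fractions={c: counts[c] / n for c in CATEGORIES},
        n_assigned=n,
        n_unassigned=len(unassigned),
        fraction_within_100kb=within_100 / n,
        fraction_within_200kb=within_200 / n,
    )


def bound_genes(
    rs: RegionSet,
    genes: Sequence[GeneRecord],
    window_bp: int = 200_000,
    anchor: AnchorMode = "summit_or_midpoint",
    label: str | None = None,
) -> GeneSet:
    """Genes with >= 1 peak anchor within ``[tss - window, tss + window]``
    (inclusive at both boundaries).  The result records each gene's
    supporting region_ids."""
    if window_bp <= 0:
        raise ValidationError(f"window_bp must be > 0, got {window_bp}")
    anchors_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_anchors = np.array([peak_anchor(iv, anchor) for iv in rs.intervals], dtype=np.int64)
    chrom_arr = [iv.chrom for iv in rs.intervals]
    for chrom in rs.chroms:
        mask = np.array([c == chrom for c in chrom_arr])
        pos = all_anchors[mask]
        idx = np.flatnonzero(mask)
        order = np.argsort(pos, kind="stable")
        anchors_by_chrom[chrom] = (pos[order], idx[order])
    support: dict[str, list[str]] = {}
    for g in genes:
        entry = anchors_by_chrom.get(g.chrom)
        if entry is None:
            continue
        pos, idx = entry
        lo = int(np.searchsorted(pos, g.tss - window_bp, side="left"))
        hi = int(np.searchsorted(pos, g.tss + window_bp, side="right"))
        if hi > lo:
            support[g.gene_id] = sorted(rs.region_ids[i] for i in idx[lo:hi])
    return GeneSet.build(
        label or f"bound_by_{rs.label}",
        support.keys(),
        stage="bound_genes",
        params={"regions": rs.label, "window_bp": window_bp, "anchor": anchor},
        support=support,
    )
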