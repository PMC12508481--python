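"""Peak classification against gene annotation and TSS-proximity statistics.

Peaks are assigned exactly one category by midpoint membership with fixed
priority promoter > exon > intron > downstream > intergenic, which partitions
any peak set (a pie-chart-compatible classification).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import (
    GenomeInterval,
    IntervalSet,
    signed_tss_distance,
    tss_set_of_genes,
)

__all__ = [
    "CATEGORIES",
    "AnnotationModel",
    "PeakAnnotation",
    "classify_peak",
    "annotate_peakset",
    "tss_proximity_fractions",
    "select_bound_tss",
    "peak_edge_distance",
]

CATEGORIES = ("promoter", "exon", "intron", "downstream", "intergenic")


@dataclass
class AnnotationModel:
    """Gene bodies (strand + gene_id), optional exons, and window sizes.

    ``promoter_window`` bp on either side of the TSS defines "promoter";
    ``downstream_window`` bp past the 3' gene end defines "downstream".
    """

    genes: IntervalSet
    exons: IntervalSet | None = None
    promoter_window: int = 1000
    downstream_window: int = 3000

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("annotation requires at least one gene")
        if self.promoter_window <= 0:
            raise ValueError("promoter_window must be positive")
        self._tss = tss_set_of_genes(self.genes)

    @property
    def tss_set(self) -> IntervalSet:
        return self._tss


@dataclass(frozen=True)
class PeakAnnotation:
    peak: GenomeInterval
    category: str
    nearest_gene: str | None
    tss_distance: int


def _point_in(pos: int, iv: GenomeInterval) -> bool:
    return iv.start <= pos < iv.end


def classify_peak(peak: GenomeInterval, model: AnnotationModel) -> PeakAnnotation:
    """Assign one category to a peak by its midpoint.

    Priority: promoter (|TSS distance| <= promoter_window), exon, intron
    (inside a gene body but no exon), downstream (within downstream_window
    past the gene's 3' end, strand-aware), intergenic otherwise.
    """
    mid = peak.midpoint
    nearest_tss, dist = signed_tss_distance(peak, model.tss_set)
    if abs(dist) <= model.promoter_window:
        return PeakAnnotation(peak, "promoter", nearest_tss.name, dist)
    if model.exons is not None:
        for exon in model.exons:
            if exon.chrom == peak.chrom and _point_in(mid, exon):
                return PeakAnnotation(peak, "exon", exon.name, dist)
    for gene in model.genes:
        if gene.chrom == peak.chrom and _point_in(mid, gene):
            return PeakAnnotation(peak, "intron", gene.name, dist)
    w = model.downstream_window
    for gene in model.genes:
        if gene.chrom != peak.chrom:
            continue
        if gene.strand == "-":
            lo, hi = gene.start - w, gene.start
        else:
            lo, hi = gene.end, gene.end + w
        if lo <= mid < hi:
            return PeakAnnotation(peak, "downstream", gene.name, dist)
    return PeakAnnotation(peak, "intergenic", nearest_tss.name, dist)


def annotate_peakset(
    peaks: IntervalSet, model: AnnotationModel
) -> tuple[pd.Series, pd.DataFrame]:
    """Classify every peak; return per-category fractions and a peak table."""
    if len(peaks) == 0:
        raise ValueError("peaks must be non-empty")
    rows = []
    for peak in peaks:
        ann = classify_peak(peak, model)
        rows.append(
            {
                "chrom": peak.chrom,
                "start": peak.start,
                "end": peak.end,
                "category": ann.category,
                "nearest_gene": ann.nearest_gene,
                "tss_distance": ann.tss_distance,
            }
        )
    table = pd.DataFrame(rows)
    fractions = (
        table["category"].value_counts(normalize=True)
        .reindex(CATEGORIES, fill_value=0.0)
    )
    return fractions, table


def tss_proximity_fractions(
    peaks: IntervalSet, tss_set: IntervalSet, thresholds: list[int]
) -> np.ndarray:
    """Fraction of peaks whose |signed TSS distance| <= t for each t.

    Monotone non-decreasing in t; thresholds must be positive ascending.
    """
    if len(peaks) == 0 or len(tss_set) == 0:
        raise ValueError("peaks and tss_set must be non-empty")
    ts = list(thresholds)
    if ts != sorted(ts) or any(t <= 0 for t in ts):
        raise ValueError("thresholds must be positive and ascending")
    dists = np.array(
        [abs(signed_tss_distance(p, tss_set)[1]) for p in peaks], dtype=float
    )
    return np.array([(dists <= t).mean() for t in ts])


def peak_edge_distance(pos: int, peaks_by_chrom: dict, chrom: str) -> float:
    """bp from a point to the nearest peak edge (0 inside a peak)."""
    best = np.inf
    for p in peaks_by_chrom.get(chrom, ()):
        d = max(p.start - pos, pos - (p.end - 1), 0)
        if d < best:
            best = d
    return best


def select_bound_tss(
    tss_set: IntervalSet, peaks: IntervalSet, max_distance: int = 3000
) -> IntervalSet:
    """TSSs whose nearest peak edge is strictly < ``max_distance`` bp away.

    A TSS exactly ``max_distance`` bp from the closest peak is excluded.
    """
    if len(tss_set) == 0 or len(peaks) == 0:
        raise ValueError("tss_set and peaks must be non-empty")
    by_chrom = peaks.by_chrom()
    kept = [
        tss
        for tss in tss_set
        if peak_edge_distance(tss.start, by_chrom, tss.chrom) < max_distance
    ]
    return IntervalSet(kept)
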