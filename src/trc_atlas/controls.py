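"""GC-matched unbound control TSS sets.

Controls are sampled by exact per-histogram-bin stratification on GC%
(computed over a fixed window around each TSS), restricted to TSSs lying at
least an exclusion distance from every peak. This makes the bound and
control GC% histograms identical bin-for-bin, so any residual difference in
skew/G4/R-loop profiles between the sets cannot be a GC-content artifact.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import peak_edge_distance
from .intervals import GenomeInterval, GenomeSequence, IntervalSet
from .seqstats import gc_fraction

__all__ = ["MatchingParams", "MatchingError", "select_matched_tss", "tss_gc_percent"]


@dataclass(frozen=True)
class MatchingParams:
    """Stratified GC-matching parameters.

    gc_window: total bp around the TSS over which GC% is computed (±1 kb by
    default). gc_bin_width: histogram bin on the [0, 1] GC scale.
    exclusion_distance: bp from any peak edge below which a candidate is
    considered bound and ineligible. n_sets control sets are drawn, pairwise
    disjoint when ``disjoint`` is set, without replacement, seeded.
    """

    gc_window: int = 2000
    gc_bin_width: float = 0.01
    exclusion_distance: int = 3000
    n_sets: int = 2
    seed: int = 0
    disjoint: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.gc_bin_width <= 1):
            raise ValueError("gc_bin_width must be in (0, 1]")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


class MatchingError(ValueError):
    """Raised when some GC bin lacks enough eligible candidates."""

    def __init__(self, shortfalls: dict[int, tuple[int, int]], bin_width: float):
        self.shortfalls = shortfalls
        lines = ", ".join(
            f"GC bin [{b * bin_width:.2f}, {(b + 1) * bin_width:.2f}): "
            f"need {need}, have {have}"
            for b, (need, have) in sorted(shortfalls.items())
        )
        super().__init__(f"deficient GC bins: {lines}")


def tss_gc_percent(genome: GenomeSequence, tss: GenomeInterval, gc_window: int) -> float:
    """GC fraction over the window centered on the TSS (forward strand).

    The window is clipped at chromosome ends; GC% is strand-symmetric so no
    reverse complement is taken.
    """
    half = gc_window // 2
    start = max(tss.start - half, 0)
    end = min(tss.start + half, genome.length(tss.chrom))
    return gc_fraction(genome.fetch(tss.chrom, start, end))


def _gc_bin(gc: float, width: float) -> int:
    return min(int(gc / width), int(1 / width))


def select_matched_tss(
    bound: IntervalSet,
    candidates: IntervalSet,
    peaks: IntervalSet,
    genome: GenomeSequence,
    params: MatchingParams = MatchingParams(),
) -> list[IntervalSet]:
    """Draw ``n_sets`` GC-matched, unbound control TSS sets.

    Each control set has the same size as ``bound`` and exactly matches its
    GC% histogram bin-for-bin. Candidates at a bound TSS position or within
    ``exclusion_distance`` of any peak edge are ineligible. Sampling is
    without replacement and deterministic under ``params.seed``; with
    ``disjoint`` the sets share no TSS.
    """
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    if len(bound) == 0:
        raise ValueError("bound set is empty")
    peaks_by_chrom = peaks.by_chrom()
    bound_keys = {(t.chrom, t.start) for t in bound}

    bound_bins: dict[int, int] = {}
    for tss in bound:
        b = _gc_bin(tss_gc_percent(genome, tss, params.gc_window), params.gc_bin_width)
        bound_bins[b] = bound_bins.get(b, 0) + 1

    eligible: dict[int, list[GenomeInterval]] = {}
    for tss in candidates.sorted():
        if (tss.chrom, tss.start) in bound_keys:
            continue
        if (
            peak_edge_distance(tss.start, peaks_by_chrom, tss.chrom)
            < params.exclusion_distance
        ):
            continue
        gc = tss_gc_percent(genome, tss, params.gc_window)
        if np.isnan(gc):
            continue
        eligible.setdefault(_gc_bin(gc, params.gc_bin_width), []).append(tss)

    need_factor = params.n_sets if params.disjoint else 1
    shortfalls = {
        b: (k * need_factor, len(eligible.get(b, ())))
        for b, k in bound_bins.items()
        if len(eligible.get(b, ())) < k * need_factor
    }
    if shortfalls:
        raise MatchingError(shortfalls, params.gc_bin_width)

    rng = np.random.default_rng(params.seed)
    sets: list[list[GenomeInterval]] = [[] for _ in range(params.n_sets)]
    for b in sorted(bound_bins):
        k = bound_bins[b]
        pool = eligible[b]
        if params.disjoint:
            picks = rng.choice(len(pool), size=k * params.n_sets, replace=False)
            for i in range(params.n_sets):
                sets[i].extend(pool[j] for j in picks[i * k : (i + 1) * k])
        else:
            for i in range(params.n_sets):
                picks = rng.choice(len(pool), size=k, replace=False)
                sets[i].extend(pool[j] for j in picks)
    return [IntervalSet(s) for s in sets]
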