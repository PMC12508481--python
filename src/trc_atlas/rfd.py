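"""Replication fork directionality and TRC-site discovery.

RFD per bin is (C - W)/(C + W) from stranded Okazaki-fragment counts:
+1 means purely rightward-moving forks (Crick excess), -1 purely leftward.
Maximal runs of bins beyond a |RFD| threshold are retained; genes fully
contained in such runs and overlapping an R-loop (DRIPc) peak define TRC
sites, each a ±flank window around the DRIPc-overlap span with two distal
same-length control windows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import (
    BinnedTrack,
    GenomeAssembly,
    GenomeInterval,
    IntervalSet,
    ParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StrandedBinnedCounts",
    "TRCParams",
    "SignedGene",
    "TRCSite",
    "compute_rfd",
    "call_high_rfd_regions",
    "genes_in_regions",
    "define_trc_sites",
    "classify_orientation",
    "read_stranded_counts",
    "write_stranded_counts",
    "sites_to_frame",
    "frame_to_sites",
]


@dataclass
class StrandedBinnedCounts:
    """Watson/Crick Okazaki-fragment read counts per fixed bin."""

    bin_size: int
    watson: dict[str, np.ndarray]
    crick: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.watson = {c: np.asarray(v) for c, v in self.watson.items()}
        self.crick = {c: np.asarray(v) for c, v in self.crick.items()}
        for chrom in self.watson:
            w, c = self.watson[chrom], self.crick[chrom]
            if len(w) != len(c):
                raise ValueError(f"{chrom}: watson/crick length mismatch")
            if (w < 0).any() or (c < 0).any():
                raise ValueError(f"{chrom}: negative counts")


@dataclass(frozen=True)
class TRCParams:
    """Thresholds and window geometry for TRC-site discovery.

    rfd_threshold: strict |RFD| cutoff for retained regions.
    min_region_bins / merge_gap_bins: run-calling parameters.
    flank: half-width of the TRC window around the DRIPc-overlap center.
    control_distance / control_length: distal control window geometry.
    min_total / smooth_bins: RFD definedness and smoothing.
    """

    rfd_threshold: float = 0.75
    min_region_bins: int = 5
    merge_gap_bins: int = 1
    flank: int = 10_000
    control_distance: int = 1_000_000
    control_length: int = 20_000
    min_total: int = 10
    smooth_bins: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.rfd_threshold <= 1):
            raise ValueError("rfd_threshold must be in (0, 1]")
        if self.control_length <= 0:
            raise ValueError("control_length must be positive")
        if self.control_distance <= self.flank:
            raise ValueError("control_distance must exceed flank")


@dataclass(frozen=True)
class SignedGene:
    """A gene tagged with the RFD sign of the region containing it."""

    gene: GenomeInterval
    sign: str  # "+" (rightward forks) or "-" (leftward)


@dataclass(frozen=True)
class TRCSite:
    """A TRC window plus its two distal controls and provenance."""

    window: GenomeInterval
    gene_id: str
    gene_strand: str
    overlap_span: GenomeInterval
    region_rfd_sign: str
    control_up: GenomeInterval
    control_down: GenomeInterval


def _box_smooth(arr: np.ndarray, half_width: int) -> np.ndarray:
    """Centered moving average over 2*half_width + 1 bins, edge-renormalized."""
    if half_width <= 0:
        return arr.astype(float)
    n = len(arr)
    cum = np.concatenate(([0.0], np.cumsum(arr, dtype=float)))
    i = np.arange(n)
    lo = np.maximum(i - half_width, 0)
    hi = np.minimum(i + half_width + 1, n)
    return (cum[hi] - cum[lo]) / (hi - lo)


def compute_rfd(
    counts: StrandedBinnedCounts, min_total: int = 10, smooth_bins: int = 2
) -> BinnedTrack:
    """RFD = (C - W)/(C + W) per bin after optional moving-average smoothing.

    Bins whose smoothed total coverage C + W falls below ``min_total`` are
    missing (RFD is undefined at zero coverage).
    """
    values = {}
    for chrom in counts.watson:
        w = _box_smooth(counts.watson[chrom], smooth_bins)
        c = _box_smooth(counts.crick[chrom], smooth_bins)
        total = w + c
        with np.errstate(invalid="ignore", divide="ignore"):
            rfd = (c - w) / np.maximum(total, 1e-300)
        rfd[total < min_total] = np.nan
        values[chrom] = rfd
    return BinnedTrack(counts.bin_size, values, "RFD")


def call_high_rfd_regions(rfd: BinnedTrack, params: TRCParams = TRCParams()) -> IntervalSet:
    """Maximal runs of bins with RFD strictly beyond ±threshold.

    Runs of one sign may bridge up to ``merge_gap_bins`` interior bins that
    are sub-threshold or missing, but never a bin qualifying for the
    opposite sign. A run must contain >= ``min_region_bins`` qualifying
    bins. Each region's name carries its sign ("+" or "-").
    """
    regions = []
    bs = rfd.bin_size
    for chrom in rfd.values:
        vals = rfd.values[chrom]
        for sign, mult in (("+", 1.0), ("-", -1.0)):
            qual = np.nan_to_num(mult * vals, nan=-np.inf) > params.rfd_threshold
            opposite = np.nan_to_num(-mult * vals, nan=-np.inf) > params.rfd_threshold
            idx = np.flatnonzero(qual)
            if len(idx) == 0:
                continue
            groups: list[list[int]] = [[idx[0]]]
            for j in idx[1:]:
                prev = groups[-1][-1]
                gap = j - prev - 1
                if gap <= params.merge_gap_bins and not opposite[prev + 1 : j].any():
                    groups[-1].append(j)
                else:
                    groups.append([j])
            for grp in groups:
                if len(grp) >= params.min_region_bins:
                    regions.append(
                        GenomeInterval(
                            chrom, grp[0] * bs, (grp[-1] + 1) * bs, ".", sign
                        )
                    )
    return IntervalSet(regions)


def genes_in_regions(genes: IntervalSet, regions: IntervalSet) -> list[SignedGene]:
    """Genes whose body is fully contained in a single region, sign-tagged."""
    if len(genes) == 0 or len(regions) == 0:
        return []
    by_chrom = regions.by_chrom()
    out = []
    for gene in genes:
        for region in by_chrom.get(gene.chrom, ()):
            if region.start <= gene.start and gene.end <= region.end:
                out.append(SignedGene(gene, region.name))
                break
    return out


def define_trc_sites(
    signed_genes: list[SignedGene],
    dripc: IntervalSet,
    params: TRCParams,
    assembly: GenomeAssembly,
) -> list[TRCSite]:
    """TRC sites from DRIPc-overlapping genes inside high-|RFD| regions.

    Per gene with at least one DRIPc overlap, the overlap span runs from the
    leftmost overlap start to the rightmost overlap end across all
    gene ∩ DRIPc-peak intersections (strand-agnostic). The TRC window is
    span-center ± flank; controls are ``control_length`` windows centered
    ``control_distance`` bp up- and downstream of the center. Sites whose
    window or either control exceeds chromosome bounds are dropped with a
    logged count.
    """
    dripc_by_chrom = dripc.by_chrom()
    sites = []
    dropped = 0
    for sg in signed_genes:
        gene = sg.gene
        lo, hi = None, None
        for peak in dripc_by_chrom.get(gene.chrom, ()):
            s = max(gene.start, peak.start)
            e = min(gene.end, peak.end)
            if s < e:
                lo = s if lo is None else min(lo, s)
                hi = e if hi is None else max(hi, e)
        if lo is None:
            continue
        center = (lo + hi) // 2
        clen = assembly.length(gene.chrom)
        half = params.control_length // 2
        bounds = [
            (center - params.flank, center + params.flank),
            (center - params.control_distance - half, center - params.control_distance + half),
            (center + params.control_distance - half, center + params.control_distance + half),
        ]
        if any(s < 0 or e > clen for s, e in bounds):
            dropped += 1
            continue
        sites.append(
            TRCSite(
                window=GenomeInterval(gene.chrom, *bounds[0], ".", gene.name),
                gene_id=gene.name,
                gene_strand=gene.strand,
                overlap_span=GenomeInterval(gene.chrom, lo, hi),
                region_rfd_sign=sg.sign,
                control_up=GenomeInterval(gene.chrom, *bounds[1]),
                control_down=GenomeInterval(gene.chrom, *bounds[2]),
            )
        )
    if dropped:
        logger.info("define_trc_sites: dropped %d sites with out-of-bounds windows", dropped)
    return sites


def classify_orientation(site: TRCSite) -> str:
    """head_on when transcription opposes the predominant fork direction.

    A + strand gene transcribes rightward; in a "-" (leftward-fork) region
    the two machineries approach each other head-on. The four strand/sign
    combinations map to {co_directional, head_on, head_on, co_directional}.
    """
    if site.gene_strand == site.region_rfd_sign:
        return "co_directional"
    return "head_on"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stranded_counts(counts: StrandedBinnedCounts, path: str | Path) -> None:
    """4-column TSV: chrom, bin_start, watson, crick."""
    with open(path, "w") as fh:
        fh.write("chrom\tbin_start\twatson\tcrick\n")
        for chrom in counts.watson:
            w, c = counts.watson[chrom], counts.crick[chrom]
            for i in range(len(w)):
                fh.write(f"{chrom}\t{i * counts.bin_size}\t{int(w[i])}\t{int(c[i])}\n")


def read_stranded_counts(
    path: str | Path, assembly: GenomeAssembly, bin_size: int
) -> StrandedBinnedCounts:
    df = pd.read_csv(path, sep="\t")
    expected = ["chrom", "bin_start", "watson", "crick"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}")
    watson, crick = {}, {}
    for chrom in assembly.names:
        n = assembly.n_bins(chrom, bin_size)
        watson[chrom] = np.zeros(n, dtype=int)
        crick[chrom] = np.zeros(n, dtype=int)
    for chrom, start, w, c in df.itertuples(index=False):
        watson[chrom][start // bin_size] = w
        crick[chrom][start // bin_size] = c
    return StrandedBinnedCounts(bin_size, watson, crick)


def sites_to_frame(sites: list[TRCSite]) -> pd.DataFrame:
    rows = []
    for site in sites:
        rows.append(
            {
                "chrom": site.window.chrom,
                "window_start": site.window.start,
                "window_end": site.window.end,
                "gene_id": site.gene_id,
                "gene_strand": site.gene_strand,
                "overlap_start": site.overlap_span.start,
                "overlap_end": site.overlap_span.end,
                "rfd_sign": site.region_rfd_sign,
                "orientation": classify_orientation(site),
                "control_up_start": site.control_up.start,
                "control_up_end": site.control_up.end,
                "control_down_start": site.control_down.start,
                "control_down_end": site.control_down.end,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "window_start", "window_end", "gene_id", "gene_strand",
            "overlap_start", "overlap_end", "rfd_sign", "orientation",
            "control_up_start", "control_up_end",
            "control_down_start", "control_down_end",
        ],
    )


def frame_to_sites(df: pd.DataFrame) -> list[TRCSite]:
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            TRCSite(
                window=GenomeInterval(
                    row.chrom, row.window_start, row.window_end, ".", row.gene_id
                ),
                gene_id=row.gene_id,
                gene_strand=row.gene_strand,
                overlap_span=GenomeInterval(row.chrom, row.overlap_start, row.overlap_end),
                region_rfd_sign=row.rfd_sign,
                control_up=GenomeInterval(row.chrom, row.control_up_start, row.control_up_end),
                control_down=GenomeInterval(
                    row.chrom, row.control_down_start, row.control_down_end
                ),
            )
        )
    return sites
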