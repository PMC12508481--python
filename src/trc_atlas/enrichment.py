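"""Coverage normalization and factor enrichment at TRC sites.

Per site, the mean normalized signal over the TRC window is compared with
the mean over its two distal control windows; the per-factor summary is the
log2 of the across-site mean ratio. A pseudocount guards zero-coverage
windows.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import BinnedTrack
from .rfd import TRCSite

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationParams",
    "EnrichmentResult",
    "normalize_track",
    "average_tracks",
    "score_trc_enrichment",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Coverage normalization mode and ratio pseudocount.

    RPKM = count / ((bin_size/1000) * (total_mapped/1e6));
    CPM  = count / (total_mapped/1e6).
    """

    bin_size: int = 100
    mode: str = "RPKM"
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.mode not in ("RPKM", "CPM"):
            raise ValueError("mode must be RPKM or CPM")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class EnrichmentResult:
    """Per-site window/control means and the per-factor log2 summary."""

    factor: str
    per_site: pd.DataFrame
    factor_log2: float
    n_dropped: int = 0


def normalize_track(
    raw: BinnedTrack, total_mapped: int, params: NormalizationParams
) -> BinnedTrack:
    """Depth- (and for RPKM, length-) normalize a raw count track."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if raw.normalization != "raw":
        raise ValueError("input track must hold raw counts")
    per_million = total_mapped / 1e6
    if params.mode == "RPKM":
        denom = (raw.bin_size / 1000) * per_million
    else:
        denom = per_million
    values = {c: v / denom for c, v in raw.values.items()}
    return BinnedTrack(raw.bin_size, values, params.mode)


def average_tracks(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Element-wise replicate mean; missing bins are excluded per position."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if t.bin_size != first.bin_size or t.normalization != first.normalization:
            raise ValueError("tracks differ in bin size or normalization")
        if set(t.values) != set(first.values) or any(
            len(t.values[c]) != len(first.values[c]) for c in first.values
        ):
            raise ValueError("tracks are on different bin grids")
    values = {}
    for chrom in first.values:
        stack = np.vstack([t.values[chrom] for t in tracks])
        ok = ~np.isnan(stack)
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            values[chrom] = np.where(
                n > 0, np.nansum(stack, axis=0) / np.maximum(n, 1), np.nan
            )
    return BinnedTrack(first.bin_size, values, first.normalization)


def score_trc_enrichment(
    track: BinnedTrack,
    sites: list[TRCSite],
    params: NormalizationParams = NormalizationParams(),
    factor: str = "factor",
    log_average: bool = False,
) -> EnrichmentResult:
    """Window-vs-controls enrichment ratio per TRC site, summarized by factor.

    ratio_i = (trc_mean_i + pc) / (mean(ctrl_up_i, ctrl_down_i) + pc).
    The factor summary is log2(mean_i ratio_i) by default, or the mean of
    per-site log2 ratios with ``log_average``. Sites whose window is
    all-missing in the track are dropped with a logged count.
    """
    if not sites:
        raise ValueError("sites must be non-empty")
    pc = params.pseudocount
    rows = []
    dropped = 0
    for i, site in enumerate(sites):
        trc = track.window_mean(site.window.chrom, site.window.start, site.window.end)
        if math.isnan(trc):
            dropped += 1
            continue
        up = track.window_mean(
            site.control_up.chrom, site.control_up.start, site.control_up.end
        )
        down = track.window_mean(
            site.control_down.chrom, site.control_down.start, site.control_down.end
        )
        ctrl = np.nanmean([up, down])
        ratio = (trc + pc) / (ctrl + pc)
        rows.append(
            {
                "site": site.gene_id,
                "trc_mean": trc,
                "ctrl_up_mean": up,
                "ctrl_down_mean": down,
                "ratio": ratio,
            }
        )
    if dropped:
        logger.info("score_trc_enrichment: dropped %d all-missing sites", dropped)
    if not rows:
        raise ValueError("all sites dropped (no signal in any TRC window)")
    per_site = pd.DataFrame(rows)
    if log_average:
        factor_log2 = float(np.log2(per_site["ratio"]).mean())
    else:
        factor_log2 = float(np.log2(per_site["ratio"].mean()))
    return EnrichmentResult(factor, per_site, factor_log2, n_dropped=dropped)
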