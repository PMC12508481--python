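"""Strand-aware aggregation of binned signal around anchor sets.

The reference-point analog of deepTools computeMatrix/plotHeatmap: one row
per anchor, columns on a symmetric offset grid, resampled from the track's
fine bins by overlap-weighted mean; rows of - strand anchors are reversed so
offsets read in the gene's direction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import BinnedTrack, IntervalSet
from .seqstats import PositionProfile

logger = logging.getLogger(__name__)

__all__ = ["SignalMatrix", "signal_matrix", "summary_profile"]


@dataclass
class SignalMatrix:
    """anchors x offsets signal values with NaN for missing cells."""

    anchors: list[str]
    offsets: np.ndarray
    values: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.anchors), len(self.offsets)):
            raise ValueError("values shape must be (n_anchors, n_offsets)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.anchors, columns=self.offsets)


def signal_matrix(
    track: BinnedTrack,
    anchors: IntervalSet,
    flank: int = 3000,
    out_bin: int = 50,
) -> SignalMatrix:
    """Per-anchor signal over [anchor - flank, anchor + flank) at out_bin bp.

    ``out_bin`` must be an integer multiple of the track bin size or vice
    versa. Each output cell is the overlap-weighted NaN-aware mean of the
    fine bins it covers; a cell is missing only when every covered fine bin
    is missing. Anchors without full flank room on their chromosome are
    dropped and counted.
    """
    bs = track.bin_size
    if out_bin % bs != 0 and bs % out_bin != 0:
        raise ValueError(
            f"out_bin {out_bin} incompatible with track bin size {bs}"
        )
    if (2 * flank) % out_bin != 0:
        raise ValueError("2*flank must be a multiple of out_bin")
    n_out = 2 * flank // out_bin
    offsets = -flank + out_bin // 2 + out_bin * np.arange(n_out)

    rows = []
    names = []
    dropped = 0
    for idx, anchor in enumerate(anchors):
        if anchor.chrom not in track.values:
            dropped += 1
            continue
        a = anchor.midpoint
        if a - flank < 0 or a + flank > track.chrom_end(anchor.chrom):
            dropped += 1
            continue
        row = np.array(
            [
                track.window_mean(
                    anchor.chrom, a - flank + k * out_bin, a - flank + (k + 1) * out_bin
                )
                for k in range(n_out)
            ]
        )
        if anchor.strand == "-":
            row = row[::-1]
        rows.append(row)
        names.append(anchor.name if anchor.name is not None else f"anchor_{idx}")
    if dropped:
        logger.info("signal_matrix: dropped %d anchors without flank room", dropped)
    values = np.vstack(rows) if rows else np.empty((0, n_out))
    return SignalMatrix(names, offsets, values, n_dropped=dropped)


def summary_profile(matrix: SignalMatrix) -> PositionProfile:
    """Column means of the signal matrix, ignoring missing cells."""
    if matrix.values.shape[0] == 0:
        raise ValueError("empty signal matrix")
    ok = ~np.isnan(matrix.values)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(
            n > 0, np.nansum(matrix.values, axis=0) / np.maximum(n, 1), np.nan
        )
    return PositionProfile(matrix.offsets, mean, n, "signal")
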