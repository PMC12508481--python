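"""Sequence-composition statistics around transcription start sites.

GC content, sliding-window GC skew, and per-base G-quadruplex propensity
scores (G4Hunter-style run scoring), aggregated into strand-aware positional
profiles around TSS sets. Positive GC skew on the non-template strand and
high G4 propensity both mark promoters prone to co-transcriptional R-loop
formation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import (
    GenomeInterval,
    GenomeSequence,
    IntervalSet,
    extract_sequence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SkewParams",
    "G4Params",
    "PositionProfile",
    "gc_fraction",
    "gc_skew",
    "g4_base_scores",
    "g4_window_scores",
    "skew_profile",
    "g4_profile",
]


@dataclass(frozen=True)
class SkewParams:
    """10 kb span around the TSS scanned with 200 bp windows sliding 1 bp."""

    flank: int = 5000
    window: int = 200
    step: int = 1

    def __post_init__(self) -> None:
        if self.window > 2 * self.flank:
            raise ValueError("window must fit inside the 2*flank span")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class G4Params:
    """2 kb span around the TSS scanned with 25 bp windows sliding 1 bp."""

    flank: int = 1000
    window: int = 25
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.flank < self.window:
            raise ValueError("flank must be >= window")


@dataclass
class PositionProfile:
    """Per-offset aggregated statistic around a set of anchors.

    Offsets are bp relative to the anchor, negative upstream in the gene's
    reading direction. ``n`` counts the anchors contributing at each offset;
    ``n_skipped`` counts anchors dropped for lacking flank room.
    """

    offsets: np.ndarray
    mean: np.ndarray
    n: np.ndarray
    stat_name: str
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "n": self.n}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _base_counts(seq: str) -> dict[str, int]:
    s = seq.upper()
    return {b: s.count(b) for b in "ACGT"}


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); NaN if no unambiguous base."""
    if not seq:
        raise ValueError("empty sequence")
    c = _base_counts(seq)
    denom = sum(c.values())
    if denom == 0:
        return float("nan")
    return (c["G"] + c["C"]) / denom


def gc_skew(seq: str) -> float:
    """(#G - #C) / (#G + #C); NaN when the sequence has no G or C."""
    if not seq:
        raise ValueError("empty sequence")
    c = _base_counts(seq)
    gc = c["G"] + c["C"]
    if gc == 0:
        return float("nan")
    return (c["G"] - c["C"]) / gc


def g4_base_scores(seq: str) -> np.ndarray:
    """Per-base G4 propensity: run scoring with magnitude capped at 4.

    Every base in a maximal run of k consecutive G scores +min(k, 4); every
    base in a run of k consecutive C scores -min(k, 4); all other bases
    (including ambiguous ones) score 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    scores = np.zeros(len(arr), dtype=float)
    for base, sign in ((ord("G"), 1.0), (ord("C"), -1.0)):
        mask = arr == base
        if not mask.any():
            continue
        # run-length encode the mask
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        for s, e in zip(starts, ends):
            scores[s:e] = sign * min(e - s, 4)
    return scores


def g4_window_scores(seq: str, window: int) -> np.ndarray:
    """Mean per-base G4 score of every ``window``-length substring."""
    base = g4_base_scores(seq)
    if len(base) < window:
        return np.empty(0)
    cum = np.concatenate(([0.0], np.cumsum(base)))
    return (cum[window:] - cum[:-window]) / window


def _window_skews(seq: str, window: int, step: int) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    g = np.concatenate(([0], np.cumsum(arr == ord("G"))))
    c = np.concatenate(([0], np.cumsum(arr == ord("C"))))
    starts = np.arange(0, len(arr) - window + 1, step)
    ng = g[starts + window] - g[starts]
    nc = c[starts + window] - c[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ng + nc > 0, (ng - nc) / np.maximum(ng + nc, 1), np.nan)


def _anchor_window(tss: GenomeInterval, flank: int) -> GenomeInterval:
    return GenomeInterval(
        tss.chrom, tss.start - flank, tss.start + flank, tss.strand
    )


def _aggregate(
    genome: GenomeSequence,
    tss_set: IntervalSet,
    flank: int,
    per_anchor,
    n_offsets: int,
    offsets: np.ndarray,
    stat_name: str,
) -> PositionProfile:
    total = np.zeros(n_offsets)
    count = np.zeros(n_offsets, dtype=int)
    skipped = 0
    for tss in tss_set:
        if tss.start - flank < 0 or tss.start + flank > genome.length(tss.chrom):
            skipped += 1
            continue
        seq = extract_sequence(genome, _anchor_window(tss, flank))
        vals = per_anchor(seq)
        ok = ~np.isnan(vals)
        total[ok] += vals[ok]
        count += ok
    if skipped:
        logger.info("%s profile: skipped %d anchors without flank room", stat_name, skipped)
    if count.sum() == 0:
        raise ValueError("no usable anchors after skipping")
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return PositionProfile(offsets, mean, count, stat_name, n_skipped=skipped)


def skew_profile(
    genome: GenomeSequence, tss_set: IntervalSet, params: SkewParams = SkewParams()
) -> PositionProfile:
    """Mean sliding-window GC skew around a TSS set, in reading direction.

    Each anchor's ±flank sequence is taken on the gene's strand (- strand
    anchors are reverse-complemented, mirroring offsets), scored with
    ``window`` bp windows sliding ``step`` bp, and averaged per offset over
    anchors. Anchors without full flank room are skipped and counted.
    """
    w, st = params.window, params.step
    starts = np.arange(0, 2 * params.flank - w + 1, st)
    offsets = starts + w // 2 - params.flank
    return _aggregate(
        genome,
        tss_set,
        params.flank,
        lambda seq: _window_skews(seq, w, st),
        len(offsets),
        offsets,
        "gc_skew",
    )


def g4_profile(
    genome: GenomeSequence,
    tss_set: IntervalSet,
    params: G4Params = G4Params(),
    aggregate: str = "absolute",
) -> PositionProfile:
    """Mean windowed G4 propensity around a TSS set.

    Window scores below ``params.threshold`` in magnitude are floored to 0
    (the reporting threshold of run-scoring G4 screens). Aggregation across
    anchors is the mean of absolute window scores by default (a G4 can form
    on either strand); ``aggregate="signed"`` keeps the sign.
    """
    if aggregate not in ("absolute", "signed"):
        raise ValueError("aggregate must be 'absolute' or 'signed'")
    w = params.window
    starts = np.arange(0, 2 * params.flank - w + 1)
    offsets = starts + w // 2 - params.flank

    def per_anchor(seq: str) -> np.ndarray:
        vals = g4_window_scores(seq, w)
        if params.threshold > 0:
            vals = np.where(np.abs(vals) < params.threshold, 0.0, vals)
        return np.abs(vals) if aggregate == "absolute" else vals

    return _aggregate(
        genome, tss_set, params.flank, per_anchor, len(offsets), offsets, "g4_score"
    )
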