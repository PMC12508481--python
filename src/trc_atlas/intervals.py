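"""Genomic coordinate model, interval algebra, and text-format I/O.

Coordinates are 0-based, half-open (BED convention) everywhere inside the
package; GTF input (1-based, closed) is converted at the parser boundary.
The TSS anchor of a gene is its ``start`` on the + strand and ``end - 1`` on
the - strand, stored as a 1 bp interval.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeAssembly",
    "GenomeInterval",
    "IntervalSet",
    "BinnedTrack",
    "GenomeSequence",
    "CoordinateError",
    "ParseError",
    "reverse_complement",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gtf_genes",
    "write_gtf_genes",
    "read_fasta",
    "write_fasta",
    "merge_overlapping",
    "signed_tss_distance",
    "extract_sequence",
    "bin_counts",
    "tss_of_gene",
    "tss_set_of_genes",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """An interval falls outside its chromosome or names an unknown one."""


class ParseError(ValueError):
    """A malformed record in a text genomic format, with its line number."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names with their lengths in bp."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        names = list(self.lengths)
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        for name, length in self.lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        object.__setattr__(self, "lengths", dict(self.lengths))

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.length(chrom) / bin_size)


@dataclass(frozen=True)
class GenomeInterval:
    """Strand-aware half-open genomic span [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid span {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def validate(self, assembly: GenomeAssembly) -> None:
        if self.end > assembly.length(self.chrom):
            raise CoordinateError(
                f"{self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {assembly.length(self.chrom)}"
            )


def _sort_key(iv: GenomeInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end)


class IntervalSet:
    """A (possibly sorted) collection of :class:`GenomeInterval`."""

    def __init__(self, intervals: Iterable[GenomeInterval] = (), sort: bool = True):
        ivs = list(intervals)
        if sort:
            ivs.sort(key=_sort_key)
        self.intervals: list[GenomeInterval] = ivs
        self.is_sorted: bool = sort or ivs == sorted(ivs, key=_sort_key)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomeInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals)"

    def sorted(self) -> "IntervalSet":
        if self.is_sorted:
            return self
        return IntervalSet(self.intervals, sort=True)

    def by_chrom(self) -> dict[str, list[GenomeInterval]]:
        out: dict[str, list[GenomeInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, assembly: GenomeAssembly | None = None) -> IntervalSet:
    """Read a BED3/BED6 file into a sorted :class:`IntervalSet`.

    Strand is "." when the column is absent; name "." maps to ``None``.
    Coordinates are validated against ``assembly`` when one is given.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name = None
            score = None
            strand = "."
            if len(fields) >= 4 and fields[3] != ".":
                name = fields[3]
            if len(fields) >= 5 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
            if len(fields) >= 6:
                strand = fields[5]
            try:
                iv = GenomeInterval(chrom, start, end, strand, name, score)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if assembly is not None:
                iv.validate(assembly)
            intervals.append(iv)
    return IntervalSet(intervals)


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED3 when no interval carries strand/name/score, else BED6."""
    six = any(
        iv.strand != "." or iv.name is not None or iv.score is not None
        for iv in iset
    )
    with open(path, "w") as fh:
        for iv in iset:
            if six:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.name if iv.name is not None else '.'}\t"
                    f"{_fmt_score(iv.score)}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# GTF-lite (gene records only)
# ---------------------------------------------------------------------------

def read_gtf_genes(path: str | Path, assembly: GenomeAssembly | None = None) -> IntervalSet:
    """Read gene records from a minimal GTF (feature == "gene").

    GTF 1-based closed coordinates are converted to 0-based half-open; the
    ``gene_id`` attribute becomes the interval name.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            try:
                start = int(fields[3]) - 1
                end = int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            strand = fields[6]
            gene_id = None
            for token in fields[8].split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gene_id = token.split(None, 1)[1].strip('"')
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            iv = GenomeInterval(fields[0], start, end, strand, gene_id)
            if assembly is not None:
                iv.validate(assembly)
            intervals.append(iv)
    return IntervalSet(intervals)


def write_gtf_genes(genes: IntervalSet, path: str | Path, source: str = "trc_atlas") -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tgene_id \"{g.name}\";\n"
            )


def tss_of_gene(gene: GenomeInterval) -> GenomeInterval:
    """1 bp TSS anchor: gene start on +, end-1 on - (reading direction)."""
    pos = gene.start if gene.strand != "-" else gene.end - 1
    return GenomeInterval(gene.chrom, pos, pos + 1, gene.strand, gene.name)


def tss_set_of_genes(genes: IntervalSet) -> IntervalSet:
    return IntervalSet(tss_of_gene(g) for g in genes)


# ---------------------------------------------------------------------------
# Binned tracks and bedGraph
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrack:
    """Fixed-bin per-chromosome signal; bin i covers [i*bin, (i+1)*bin).

    Missing data is NaN; means over windows ignore missing bins.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @classmethod
    def zeros(cls, assembly: GenomeAssembly, bin_size: int, normalization: str = "raw"):
        return cls(
            bin_size,
            {c: np.zeros(assembly.n_bins(c, bin_size)) for c in assembly.names},
            normalization,
        )

    @classmethod
    def missing(cls, assembly: GenomeAssembly, bin_size: int, normalization: str = "other"):
        return cls(
            bin_size,
            {c: np.full(assembly.n_bins(c, bin_size), np.nan) for c in assembly.names},
            normalization,
        )

    def chrom_end(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.bin_size

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Overlap-weighted mean of bin values over [start, end), NaN-aware.

        Partial bins at the window edges contribute in proportion to their
        overlap with the window. All-missing windows return NaN.
        """
        if chrom not in self.values:
            return float("nan")
        vals = self.values[chrom]
        bs = self.bin_size
        start = max(start, 0)
        end = min(end, len(vals) * bs)
        if end <= start:
            return float("nan")
        j0 = start // bs
        j1 = (end - 1) // bs + 1
        sub = vals[j0:j1]
        edges = np.arange(j0, j1 + 1) * bs
        weights = np.minimum(edges[1:], end) - np.maximum(edges[:-1], start)
        ok = ~np.isnan(sub)
        denom = weights[ok].sum()
        if denom == 0:
            return float("nan")
        return float((sub[ok] * weights[ok]).sum() / denom)


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write non-missing bins, merging runs of identical adjacent values."""
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            bs = track.bin_size
            i = 0
            n = len(vals)
            while i < n:
                if np.isnan(vals[i]):
                    i += 1
                    continue
                j = i + 1
                while j < n and not np.isnan(vals[j]) and vals[j] == vals[i]:
                    j += 1
                fh.write(f"{chrom}\t{i * bs}\t{j * bs}\t{_fmt_score(vals[i])}\n")
                i = j


def read_bedgraph(
    path: str | Path,
    assembly: GenomeAssembly,
    bin_size: int,
    normalization: str = "other",
) -> BinnedTrack:
    """Read a bedGraph onto a fixed bin grid; uncovered bins become NaN.

    Records must be aligned to the bin grid (starts at multiples of
    ``bin_size``; ends likewise or at the chromosome end).
    """
    track = BinnedTrack.missing(assembly, bin_size, normalization)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = (
                fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
            )
            if chrom not in track.values:
                raise CoordinateError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            clen = assembly.length(chrom)
            if start % bin_size != 0 or (end % bin_size != 0 and end != clen):
                raise ParseError(
                    f"{path}:{lineno}: record not aligned to {bin_size} bp bins"
                )
            if end > clen:
                raise CoordinateError(f"{path}:{lineno}: record exceeds chromosome")
            j0 = start // bin_size
            j1 = math.ceil(end / bin_size)
            track.values[chrom][j0:j1] = value
    return track


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class GenomeSequence:
    """Uniform fetch interface over a FASTA file (pyfaidx) or in-memory dict."""

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {c: str(s).upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, read_ahead=None)
        obj = cls.__new__(cls)
        obj._seqs = None
        obj._fasta = fa
        return obj

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "GenomeSequence":
        return cls(seqs)

    @property
    def assembly(self) -> GenomeAssembly:
        if self._seqs is not None:
            return GenomeAssembly({c: len(s) for c, s in self._seqs.items()})
        return GenomeAssembly({c: len(self._fasta[c]) for c in self._fasta.keys()})

    def length(self, chrom: str) -> int:
        return self.assembly.length(chrom)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand uppercase sequence of [start, end)."""
        if self._seqs is not None:
            if chrom not in self._seqs:
                raise CoordinateError(f"unknown chromosome {chrom!r}")
            seq = self._seqs[chrom]
            if not (0 <= start <= end <= len(seq)):
                raise CoordinateError(f"{chrom}:{start}-{end} out of bounds")
            return seq[start:end]
        if chrom not in self._fasta.keys():
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        clen = len(self._fasta[chrom])
        if not (0 <= start <= end <= clen):
            raise CoordinateError(f"{chrom}:{start}-{end} out of bounds")
        return str(self._fasta[chrom][start:end]).upper()


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> GenomeSequence:
    return GenomeSequence.from_fasta(path)


def extract_sequence(genome: GenomeSequence, interval: GenomeInterval) -> str:
    """Sequence of ``interval``; reverse-complemented on the - strand.

    Out-of-bounds intervals raise :class:`CoordinateError` (no silent
    clipping).
    """
    seq = genome.fetch(interval.chrom, interval.start, interval.end)
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_overlapping(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals whose gap is <= ``max_gap`` bp (bedtools merge analog).

    Output intervals are pairwise non-overlapping with inter-interval gaps
    > ``max_gap``; at ``max_gap = 0`` the union of covered bp is preserved.
    Name, score and strand are dropped.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    merged: list[GenomeInterval] = []
    for iv in iset.sorted():
        if (
            merged
            and iv.chrom == merged[-1].chrom
            and iv.start - merged[-1].end <= max_gap
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomeInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomeInterval(iv.chrom, iv.start, iv.end))
    return IntervalSet(merged, sort=False)


def signed_tss_distance(
    query: GenomeInterval, tss_set: IntervalSet
) -> tuple[GenomeInterval, int]:
    """Nearest TSS to the query midpoint and the signed distance to it.

    The sign is read in the gene's direction: negative upstream of the TSS,
    positive downstream. Ties break on smaller absolute distance, then on
    the leftmost (chrom, start) TSS.
    """
    if len(tss_set) == 0:
        raise ValueError("tss_set must be non-empty")
    mid = query.midpoint
    best: tuple | None = None
    for tss in tss_set.sorted():
        if tss.chrom != query.chrom:
            continue
        delta = mid - tss.start
        if tss.strand == "-":
            delta = -delta
        key = (abs(delta), tss.chrom, tss.start)
        if best is None or key < best[0]:
            best = (key, tss, delta)
    if best is None:
        raise ValueError(f"no TSS on chromosome {query.chrom!r}")
    return best[1], best[2]


def bin_counts(
    positions: Sequence[tuple[str, int]],
    assembly: GenomeAssembly,
    bin_size: int,
) -> BinnedTrack:
    """Histogram point positions into a raw-count :class:`BinnedTrack`.

    A position exactly at a bin boundary b*bin falls in bin b (half-open
    convention). Total over all bins equals the number of positions.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    track = BinnedTrack.zeros(assembly, bin_size, "raw")
    for chrom, pos in positions:
        clen = assembly.length(chrom)
        if not (0 <= pos < clen):
            raise CoordinateError(f"position {chrom}:{pos} out of bounds")
        track.values[chrom][pos // bin_size] += 1
    return track
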