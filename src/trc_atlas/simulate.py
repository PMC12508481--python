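"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume:
genomes with controllable GC%, strand-asymmetric GC skew planted downstream
of chosen promoters and short CGG tracts at chosen promoters; stranded
OK-seq counts whose expected RFD is a step (optionally ramped) function of
planted replication origins; binned ChIP coverage with planted fold
enrichment; R-loop (DRIPc) peaks over a chosen gene subset; and peak sets at
chosen promoters. Every generator is a pure function of its config and
returns a truth record sufficient to score recovery downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import (
    BinnedTrack,
    GenomeAssembly,
    GenomeInterval,
    GenomeSequence,
    IntervalSet,
    tss_set_of_genes,
)
from .rfd import StrandedBinnedCounts

__all__ = [
    "SimConfig",
    "make_annotation",
    "make_genome",
    "simulate_okseq",
    "simulate_chip",
    "simulate_dripc",
    "make_peaks_at_tss",
    "true_rfd_profile",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Generative conditions for the synthetic study system.

    Defaults encode the standard synthetic configuration the analyses are
    exercised under: a ~1 Mb chromosome of background GC 0.45, genes of
    5-15 kb, GC-skew amplitude 0.3 planted over the first 1 kb downstream of
    designated promoters, short CGG tracts (n < 10), OK-seq depth 200
    reads/bin at 1 kb bins, ChIP background depth 50 reads/bin at 100 bp
    bins, and DRIPc peaks over half the genes.
    """

    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 1_000_000})
    gc: float = 0.45
    skew_amplitude: float = 0.3
    skew_region: int = 1000
    n_genes: int = 60
    gene_length: tuple = (5000, 15000)
    min_gene_gap: int = 1000
    cgg_repeat_counts: tuple = (4, 5, 6, 7, 8, 9)
    origin_positions: dict | None = None
    okseq_bin_size: int = 1000
    okseq_depth: float = 200.0
    okseq_ramp: int = 0
    chip_bin_size: int = 100
    chip_background_depth: float = 50.0
    dripc_gene_fraction: float = 0.5
    dripc_peak_length: tuple = (500, 2000)

    def __post_init__(self) -> None:
        if not (0 <= self.gc <= 1):
            raise ValueError("gc must be in [0, 1]")
        if not (0 <= self.dripc_gene_fraction <= 1):
            raise ValueError("dripc_gene_fraction must be in [0, 1]")
        if self.okseq_depth < 0 or self.chip_background_depth < 0:
            raise ValueError("depths must be >= 0")

    @property
    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(self.chrom_lengths)

    def rng(self, stream: int) -> np.random.Generator:
        # independent substream per generator so outputs compose reproducibly
        return np.random.default_rng([self.seed, stream])


def make_annotation(cfg: SimConfig) -> tuple[IntervalSet, IntervalSet]:
    """Non-overlapping genes with random strands, plus their TSS anchors.

    Genes are packed chromosome by chromosome with at least
    ``min_gene_gap`` bp between them, leaving a flank margin at chromosome
    ends so promoter-centered windows fit.
    """
    rng = cfg.rng(1)
    assembly = cfg.assembly
    per_chrom = np.diff(
        np.round(np.linspace(0, cfg.n_genes, len(assembly.names) + 1)).astype(int)
    )
    genes = []
    gene_idx = 0
    margin = 6000  # keeps ±5 kb profile windows inside the chromosome
    for chrom, n in zip(assembly.names, per_chrom):
        if n == 0:
            continue
        clen = assembly.length(chrom)
        lengths = rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1, size=n)
        occupied = lengths.sum() + (n - 1) * cfg.min_gene_gap
        free = clen - 2 * margin - occupied
        if free < 0:
            raise ValueError(
                f"cannot pack {n} genes of {cfg.gene_length} bp on {chrom} "
                f"({clen} bp)"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=n))
        pos = margin
        prev_cut = 0
        for i in range(n):
            pos += cuts[i] - prev_cut
            prev_cut = cuts[i]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GenomeInterval(
                    chrom, int(pos), int(pos + lengths[i]), strand, f"gene_{gene_idx:04d}"
                )
            )
            pos += lengths[i] + cfg.min_gene_gap
            gene_idx += 1
    gene_set = IntervalSet(genes)
    return gene_set, tss_set_of_genes(gene_set)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=probs)]


def make_genome(
    cfg: SimConfig,
    skewed_tss: IntervalSet | None = None,
    cgg_tss: IntervalSet | None = None,
) -> tuple[GenomeSequence, dict]:
    """I.i.d. background genome with planted skew and CGG promoter tracts.

    Downstream [0, skew_region) of each skewed TSS (reading direction), G/C
    bases are re-drawn so the non-template strand carries a G-over-C excess
    of ``skew_amplitude``. For each TSS in ``cgg_tss``, a (CGG)_n tract
    (n cycling through ``cgg_repeat_counts``) is written immediately
    downstream of the TSS on the gene strand. The truth record lists every
    planted feature.
    """
    rng = cfg.rng(2)
    chroms = {}
    for chrom, clen in cfg.chrom_lengths.items():
        chroms[chrom] = _random_bases(rng, clen, cfg.gc)
    truth: dict = {"skewed_tss": [], "cgg_tracts": []}

    G, C = ord("G"), ord("C")
    if skewed_tss is not None:
        for tss in skewed_tss:
            arr = chroms[tss.chrom]
            if tss.strand == "-":
                start, end = max(tss.start - cfg.skew_region + 1, 0), tss.start + 1
                p_g = (1 - cfg.skew_amplitude) / 2  # C excess on forward strand
            else:
                start, end = tss.start, min(tss.start + cfg.skew_region, len(arr))
                p_g = (1 + cfg.skew_amplitude) / 2
            seg = arr[start:end]
            is_gc = (seg == G) | (seg == C)
            n_gc = int(is_gc.sum())
            seg[is_gc] = np.where(rng.random(n_gc) < p_g, G, C)
            truth["skewed_tss"].append(
                {"chrom": tss.chrom, "pos": tss.start, "strand": tss.strand}
            )

    if cgg_tss is not None:
        for i, tss in enumerate(cgg_tss):
            n_rep = cfg.cgg_repeat_counts[i % len(cfg.cgg_repeat_counts)]
            tract = "CGG" * n_rep
            if tss.strand == "-":
                from .intervals import reverse_complement

                tract_fwd = reverse_complement(tract)
                start = tss.start + 1 - len(tract)
            else:
                tract_fwd = tract
                start = tss.start
            if start < 0 or start + len(tract_fwd) > len(chroms[tss.chrom]):
                raise ValueError(f"CGG tract at {tss.chrom}:{tss.start} exceeds chromosome")
            chroms[tss.chrom][start : start + len(tract_fwd)] = np.frombuffer(
                tract_fwd.encode(), dtype=np.uint8
            )
            truth["cgg_tracts"].append(
                {"chrom": tss.chrom, "start": int(start), "n_repeats": int(n_rep),
                 "strand": tss.strand}
            )
    seqs = {c: arr.tobytes().decode("ascii") for c, arr in chroms.items()}
    return GenomeSequence.from_dict(seqs), truth


def true_rfd_profile(
    origins: np.ndarray, positions: np.ndarray, ramp: int = 0
) -> np.ndarray:
    """Expected RFD at ``positions`` for forks emanating from ``origins``.

    +1 immediately right of an origin up to the midpoint to the next origin,
    -1 beyond (i.e., approaching the next origin from its left); -1 left of
    the first origin, +1 right of the last. With ``ramp`` > 0 the ±1 steps
    at origins and midpoints become linear transitions of that width.
    """
    origins = np.sort(np.asarray(origins, dtype=float))
    if len(origins) == 0:
        raise ValueError("at least one origin is required")
    # breakpoints where RFD flips: +1 at origins, -1 at inter-origin midpoints
    step = np.full(len(positions), -1.0)
    flips = []
    for i, o in enumerate(origins):
        flips.append((o, +1.0))
        if i + 1 < len(origins):
            flips.append(((o + origins[i + 1]) / 2, -1.0))
    r = np.full(len(positions), -1.0)
    for x, target in flips:
        if ramp > 0:
            t = np.clip((positions - (x - ramp / 2)) / ramp, 0.0, 1.0)
        else:
            t = (positions >= x).astype(float)
        r = r + t * (target - r) * (positions >= x - ramp / 2)
    return np.clip(r, -1.0, 1.0)


def simulate_okseq(
    cfg: SimConfig,
    origins: dict | None = None,
    uniform: bool = False,
) -> tuple[StrandedBinnedCounts, BinnedTrack]:
    """Stranded OK-seq counts per bin plus the true RFD track.

    Per bin, total reads ~ Poisson(okseq_depth) and Crick reads ~
    Binomial(total, (1 + r)/2) where r is the true RFD at the bin center.
    ``uniform`` overrides the origin profile with r = 0 everywhere.
    """
    rng = cfg.rng(3)
    assembly = cfg.assembly
    if origins is None:
        origins = cfg.origin_positions or {
            c: (0.25 * assembly.length(c), 0.75 * assembly.length(c))
            for c in assembly.names
        }
    bs = cfg.okseq_bin_size
    watson, crick, truth = {}, {}, {}
    for chrom in assembly.names:
        n = assembly.n_bins(chrom, bs)
        centers = (np.arange(n) + 0.5) * bs
        if uniform:
            r = np.zeros(n)
        else:
            ori = np.asarray(origins.get(chrom, ()), dtype=float)
            if len(ori) == 0:
                raise ValueError(f"no origins on {chrom} (use uniform=True for r=0)")
            r = true_rfd_profile(ori, centers, ramp=cfg.okseq_ramp)
        total = rng.poisson(cfg.okseq_depth, size=n)
        c = rng.binomial(total, (1 + r) / 2)
        watson[chrom] = total - c
        crick[chrom] = c
        truth[chrom] = r
    return (
        StrandedBinnedCounts(bs, watson, crick),
        BinnedTrack(bs, truth, "RFD"),
    )


def simulate_chip(
    cfg: SimConfig,
    planted: list[tuple[GenomeInterval, float]] = (),
) -> tuple[BinnedTrack, int]:
    """Poisson ChIP counts with planted fold enrichment at chosen sites.

    Per-bin counts ~ Poisson(background_depth * fold(bin)), where fold(bin)
    is the planted fold for bins whose center lies inside a planted site and
    1 elsewhere. Returns the raw track and the total mapped count.
    """
    rng = cfg.rng(4)
    assembly = cfg.assembly
    bs = cfg.chip_bin_size
    values = {}
    for chrom in assembly.names:
        n = assembly.n_bins(chrom, bs)
        fold = np.ones(n)
        for site, f in planted:
            if f < 1:
                raise ValueError("planted folds must be >= 1")
            if site.chrom != chrom:
                continue
            centers = (np.arange(n) + 0.5) * bs
            fold[(centers >= site.start) & (centers < site.end)] = f
        values[chrom] = rng.poisson(cfg.chip_background_depth * fold, size=n).astype(float)
    track = BinnedTrack(bs, values, "raw")
    total = int(sum(v.sum() for v in track.values.values()))
    return track, total


def simulate_dripc(
    cfg: SimConfig, genes: IntervalSet
) -> tuple[IntervalSet, list[str]]:
    """One R-loop peak inside each of a seeded subset of gene bodies.

    round(dripc_gene_fraction * n_genes) genes are chosen; each gets one
    peak of seeded length within its body. Returns the peak set and the
    chosen gene ids (the truth subset).
    """
    rng = cfg.rng(5)
    n_pick = round(cfg.dripc_gene_fraction * len(genes))
    order = rng.permutation(len(genes))[:n_pick]
    peaks = []
    chosen = []
    for idx in sorted(order):
        gene = genes[int(idx)]
        max_len = min(cfg.dripc_peak_length[1], len(gene))
        min_len = min(cfg.dripc_peak_length[0], max_len)
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(gene.start, gene.end - length + 1))
        peaks.append(GenomeInterval(gene.chrom, start, start + length, ".", gene.name))
        chosen.append(gene.name)
    return IntervalSet(peaks), sorted(chosen)


def make_peaks_at_tss(
    cfg: SimConfig, tss_subset: IntervalSet, peak_halfwidth: int = 150
) -> IntervalSet:
    """A binding-site peak centered on each TSS of a chosen subset."""
    peaks = []
    for tss in tss_subset:
        start = max(tss.start - peak_halfwidth, 0)
        peaks.append(
            GenomeInterval(tss.chrom, start, tss.start + peak_halfwidth, ".", tss.name)
        )
    return IntervalSet(peaks)
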