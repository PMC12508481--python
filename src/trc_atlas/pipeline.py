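"""End-to-end orchestration of the two analyses with a config file.

``run_tss_structure_analysis`` profiles bound vs GC-matched control TSS sets
(GC skew, G4 propensity, signal metaprofile); ``run_trc_enrichment_analysis``
derives TRC sites from OK-seq RFD plus DRIPc peaks and scores factor tracks
against them. Both write TSV outputs plus a manifest recording every
parameter and input checksum, and are byte-deterministic under a fixed seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, controls, enrichment, metaprofile, rfd, seqstats
from .intervals import (
    GenomeAssembly,
    GenomeSequence,
    read_bed,
    read_bedgraph,
    read_gtf_genes,
    write_bed,
    write_bedgraph,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_tss_structure_analysis", "run_trc_enrichment_analysis"]


@dataclass
class RunConfig:
    """Input paths and per-stage parameter blocks for a pipeline run."""

    outdir: str
    seed: int = 0
    # tss-structure inputs
    fasta: str | None = None
    tss_bed: str | None = None
    peaks_bed: str | None = None
    signal_bedgraph: str | None = None
    signal_bin_size: int = 50
    bound_max_distance: int = 3000
    metaprofile_flank: int = 3000
    metaprofile_bin: int = 50
    skew: seqstats.SkewParams = field(default_factory=seqstats.SkewParams)
    g4: seqstats.G4Params = field(default_factory=seqstats.G4Params)
    matching: controls.MatchingParams = field(default_factory=controls.MatchingParams)
    # trc-enrichment inputs
    okseq_counts: str | None = None
    okseq_bin_size: int = 1000
    genes_gtf: str | None = None
    dripc_bed: str | None = None
    factor_tracks: dict = field(default_factory=dict)  # name -> bedgraph path
    factor_totals: dict = field(default_factory=dict)  # name -> total mapped
    chrom_lengths: dict = field(default_factory=dict)
    trc: rfd.TRCParams = field(default_factory=rfd.TRCParams)
    normalization: enrichment.NormalizationParams = field(
        default_factory=enrichment.NormalizationParams
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        blocks = {
            "skew": seqstats.SkewParams,
            "g4": seqstats.G4Params,
            "matching": controls.MatchingParams,
            "trc": rfd.TRCParams,
            "normalization": enrichment.NormalizationParams,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in blocks:
                kwargs[key] = blocks[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _params_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    return obj


def _write_manifest(outdir: Path, stage: str, cfg: RunConfig, inputs: dict, counts: dict):
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "parameters": {
            k: _params_dict(getattr(cfg, k))
            for k in (
                "bound_max_distance", "metaprofile_flank", "metaprofile_bin",
                "skew", "g4", "matching", "trc", "normalization",
            )
        },
        "inputs": {k: {"path": str(v), "md5": _checksum(v)} for k, v in inputs.items() if v},
        "counts": counts,
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_tss_structure_analysis(cfg: RunConfig) -> dict:
    """Bound/control TSS selection plus skew, G4 and signal metaprofiles.

    Returns the three anchor sets and their profiles; writes BEDs, profile
    TSVs and a manifest under ``cfg.outdir``.
    """
    for req in ("fasta", "tss_bed", "peaks_bed"):
        if getattr(cfg, req) is None:
            raise ValueError(f"tss-structure analysis requires {req}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = GenomeSequence.from_fasta(cfg.fasta)
    assembly = genome.assembly
    tss_all = read_bed(cfg.tss_bed, assembly)
    peaks = read_bed(cfg.peaks_bed, assembly)

    bound = annotate.select_bound_tss(tss_all, peaks, cfg.bound_max_distance)
    if len(bound) == 0:
        raise ValueError("no bound TSS selected")
    matching = dataclasses.replace(cfg.matching, seed=cfg.seed)
    ctrl_sets = controls.select_matched_tss(bound, tss_all, peaks, genome, matching)

    anchor_sets = {"bound": bound}
    for i, ctrl in enumerate(ctrl_sets, start=1):
        anchor_sets[f"control_{i}"] = ctrl

    track = None
    if cfg.signal_bedgraph:
        track = read_bedgraph(cfg.signal_bedgraph, assembly, cfg.signal_bin_size)

    results: dict = {"anchor_sets": anchor_sets, "profiles": {}}
    counts = {}
    for name, anchors in anchor_sets.items():
        write_bed(anchors, outdir / f"{name}_tss.bed")
        counts[name] = len(anchors)
        profs = {
            "skew": seqstats.skew_profile(genome, anchors, cfg.skew),
            "g4": seqstats.g4_profile(genome, anchors, cfg.g4),
        }
        if track is not None:
            mat = metaprofile.signal_matrix(
                track, anchors, cfg.metaprofile_flank, cfg.metaprofile_bin
            )
            profs["signal"] = metaprofile.summary_profile(mat)
        for stat, prof in profs.items():
            prof.write_tsv(outdir / f"{stat}_{name}.tsv")
        results["profiles"][name] = profs

    _write_manifest(
        outdir, "tss_structure", cfg,
        {"fasta": cfg.fasta, "tss_bed": cfg.tss_bed, "peaks_bed": cfg.peaks_bed,
         "signal_bedgraph": cfg.signal_bedgraph},
        counts,
    )
    return results


def run_trc_enrichment_analysis(cfg: RunConfig) -> dict:
    """RFD -> high-|RFD| regions -> TRC sites -> per-factor enrichment.

    Zero TRC sites yields an explicit empty-result status rather than an
    error. The factor summary table is ordered by descending log2 ratio.
    """
    for req in ("okseq_counts", "genes_gtf", "dripc_bed"):
        if getattr(cfg, req) is None:
            raise ValueError(f"trc-enrichment analysis requires {req}")
    if not cfg.chrom_lengths:
        raise ValueError("trc-enrichment analysis requires chrom_lengths")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembly = GenomeAssembly(cfg.chrom_lengths)

    counts = rfd.read_stranded_counts(cfg.okseq_counts, assembly, cfg.okseq_bin_size)
    genes = read_gtf_genes(cfg.genes_gtf, assembly)
    dripc = read_bed(cfg.dripc_bed, assembly)

    rfd_track = rfd.compute_rfd(counts, cfg.trc.min_total, cfg.trc.smooth_bins)
    write_bedgraph(rfd_track, outdir / "rfd.bedgraph")
    regions = rfd.call_high_rfd_regions(rfd_track, cfg.trc)
    write_bed(regions, outdir / "high_rfd_regions.bed")
    signed = rfd.genes_in_regions(genes, regions)
    sites = rfd.define_trc_sites(signed, dripc, cfg.trc, assembly)
    site_frame = rfd.sites_to_frame(sites)
    site_frame.to_csv(outdir / "trc_sites.tsv", sep="\t", index=False)

    results: dict = {"sites": sites, "factors": {}, "status": "ok"}
    if not sites:
        results["status"] = "no_trc_sites"
        pd.DataFrame(columns=["factor", "factor_log2", "n_sites"]).to_csv(
            outdir / "enrichment_summary.tsv", sep="\t", index=False
        )
        _write_manifest(outdir, "trc_enrichment", cfg,
                        {"okseq_counts": cfg.okseq_counts, "genes_gtf": cfg.genes_gtf,
                         "dripc_bed": cfg.dripc_bed},
                        {"n_sites": 0})
        return results

    summary_rows = []
    for factor in sorted(cfg.factor_tracks):
        raw = read_bedgraph(
            cfg.factor_tracks[factor], assembly, cfg.normalization.bin_size, "raw"
        )
        for chrom in raw.values:  # uncovered bins in a raw count track are zeros
            vals = raw.values[chrom]
            vals[pd.isna(vals)] = 0.0
        raw.normalization = "raw"
        track = enrichment.normalize_track(
            raw, int(cfg.factor_totals[factor]), cfg.normalization
        )
        result = enrichment.score_trc_enrichment(
            track, sites, cfg.normalization, factor=factor
        )
        result.per_site.to_csv(outdir / f"enrichment_{factor}.tsv", sep="\t", index=False)
        results["factors"][factor] = result
        summary_rows.append(
            {"factor": factor, "factor_log2": result.factor_log2,
             "n_sites": len(result.per_site)}
        )
    summary = pd.DataFrame(summary_rows).sort_values(
        "factor_log2", ascending=False, kind="mergesort"
    )
    summary.to_csv(outdir / "enrichment_summary.tsv", sep="\t", index=False)
    results["summary"] = summary

    _write_manifest(
        outdir, "trc_enrichment", cfg,
        {"okseq_counts": cfg.okseq_counts, "genes_gtf": cfg.genes_gtf,
         "dripc_bed": cfg.dripc_bed,
         **{f"track_{k}": v for k, v in cfg.factor_tracks.items()}},
        {"n_sites": len(sites),
         "n_regions": len(regions),
         "n_contained_genes": len(signed)},
    )
    return results
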