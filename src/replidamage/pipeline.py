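"""End-to-end orchestration of the three analysis arms.

Each ``run_*`` function reads its inputs from a :class:`PipelineConfig`,
executes the stage chain, writes every intermediate plus a JSON run
manifest (parameters, replicate correlations, output checksums) into the
output directory, and returns the manifest.  A stage failure aborts with
the stage name attached so a broken input is attributable.

Stage chains
------------
damage arm:   count -> RPKM -> replicate mean -> log2 difference
              -> HMM segmentation -> domain calls -> late-domain overlap
              -> per-bin timing correlation -> metadomain profile
histone arm:  count -> RPKM -> replicate mean -> top-peak scaling
              -> TSS aggregate -> genic/intergenic partition
origin arm:   count -> RPKM -> pairwise correlation matrix
              -> origin-anchored aggregate
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .coverage import (
    BinnedTrack,
    bin_genome,
    correlation_matrix,
    count_reads,
    mean_tracks,
    pearson,
    rpkm_normalize,
    write_track,
)
from .diffsignal import log2_difference, scale_to_reference
from .domains import bin_correlation, count_overlaps, metadomain_profile
from .hmm import call_domains, positive_domains, segment
from .profiles import AnchorSet, anchor_aggregate, genic_intergenic_partition

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StageError",
    "run_damage_analysis",
    "run_h4k20me1_analysis",
    "run_origin_analysis",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs and parameters for the pipeline runs.

    ``reads`` maps condition name (e.g. ``control``, ``treatment``,
    ``early``, ``late``, or BrdU condition labels) to a list of replicate
    BED paths.  Default binning follows the analysis conventions: 5 kb
    non-overlapping bins for the damage differential and 10 kb windows
    stepping every 1 kb for histone-mark and origin-activity profiles.
    """

    chrom_sizes: str = ""
    reads: dict[str, list[str]] = field(default_factory=dict)
    timing_bedgraph: str = ""
    timing_domains_bed: str = ""
    genes_bed: str = ""
    tss_bed: str = ""
    origins_bed: str = ""
    out_dir: str = "results"

    damage_bin_width: int = 5000
    damage_step: int = 5000
    profile_bin_width: int = 10_000
    profile_step: int = 1000

    top_frac: float = 0.05
    scale_reference: str = "late"  # which condition the other is scaled to

    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    hmm_min_bins: int = 1
    hmm_variance_floor: float = 1e-6
    seed: int = 0

    metadomain_n_inner: int = 50
    metadomain_n_flank: int = 25
    overlap_min_bp: int = 1

    anchor_flank: int = 2000
    anchor_n_bins: int = 81

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self, required: Sequence[str]) -> None:
        for name in required:
            p = getattr(self, name)
            if not p:
                raise StageError("config", f"missing required input {name!r}")
            if not Path(p).exists():
                raise StageError("config", f"{name} file not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _finish_manifest(manifest: dict, out: Path) -> dict:
    manifest["outputs"] = {
        name: {"path": str(p), "sha256": _sha256(Path(p))}
        for name, p in manifest.pop("_files", {}).items()
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    manifest["manifest_path"] = str(path)
    return manifest


def _load_condition_tracks(
    config: PipelineConfig,
    condition: str,
    bins,
    stage: str,
) -> tuple[list[BinnedTrack], list[int]]:
    """Count and RPKM-normalize every replicate BED of one condition."""
    paths = config.reads.get(condition, [])
    if not paths:
        raise StageError(stage, f"no read files configured for {condition!r}")
    tracks, totals = [], []
    for p in paths:
        if not Path(p).exists():
            raise StageError(stage, f"read file not found: {p}")
        reads = io.read_reads_bed(p, condition_label=condition)
        raw, skipped = count_reads(reads, bins)
        if skipped:
            logger.info("%s: %d reads skipped in %s", condition, skipped, p)
        tracks.append(rpkm_normalize(raw, len(reads)))
        totals.append(len(reads))
    return tracks, totals


def _replicate_correlations(tracks: list[BinnedTrack]) -> list[float]:
    out = []
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            out.append(pearson(tracks[i], tracks[j]))
    return out


def run_damage_analysis(config: PipelineConfig) -> dict:
    """Damage-mark differential arm: from reads to timing-linked domains.

    Requires ``reads['control']`` and ``reads['treatment']`` (replicates
    allowed), the chromosome sizes, the timing bedGraph and the
    timing-domain BED (with early/late class names).
    """
    config.validate_paths(
        ["chrom_sizes", "timing_bedgraph", "timing_domains_bed"]
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sizes = io.read_chrom_sizes(config.chrom_sizes)
    bins = bin_genome(sizes, config.damage_bin_width, config.damage_step)

    manifest: dict = {
        "arm": "damage",
        "version": __version__,
        "parameters": asdict(config),
        "_files": {},
    }

    cond_tracks: dict[str, BinnedTrack] = {}
    for cond in ("control", "treatment"):
        tracks, totals = _load_condition_tracks(config, cond, bins, "coverage")
        manifest[f"replicate_pearson_{cond}"] = _replicate_correlations(tracks)
        manifest[f"total_reads_{cond}"] = totals
        mean = mean_tracks(tracks)
        cond_tracks[cond] = mean
        path = out / f"rpkm_{cond}.bedgraph"
        write_track(mean, path)
        manifest["_files"][f"rpkm_{cond}"] = path

    try:
        diff = log2_difference(cond_tracks["treatment"], cond_tracks["control"])
    except ValueError as exc:
        raise StageError("log2_difference", str(exc)) from exc
    path = out / "log2_difference.bedgraph"
    write_track(diff, path)
    manifest["_files"]["log2_difference"] = path

    obs_by_chrom = {c: v for c, (_, _, v) in diff.by_chrom().items()}
    try:
        result = segment(
            obs_by_chrom,
            tol=config.hmm_tol,
            max_iter=config.hmm_max_iter,
            variance_floor=config.hmm_variance_floor,
        )
    except ValueError as exc:
        raise StageError("hmm_segmentation", str(exc)) from exc
    manifest["hmm"] = {
        "converged": result.converged,
        "iterations": result.n_iterations,
        "log_likelihood": result.log_likelihood,
        "means": result.params.means.tolist(),
        "variances": result.params.variances.tolist(),
        "transitions": result.params.transitions.tolist(),
        "initial": result.params.initial.tolist(),
        "loglik_trace": result.loglik_trace,
    }

    domains = call_domains(result, diff.bins, min_bins=config.hmm_min_bins)
    pos = positive_domains(domains)
    manifest["n_positive_domains"] = len(pos)
    path = out / "gh2av_domains.bed"
    io.write_bed_intervals(
        [
            (
                d.chrom, d.start, d.end, d.state,
                int(np.clip(round(1000 * d.mean_posterior), 0, 1000)), ".",
            )
            for d in domains
        ],
        path,
    )
    manifest["_files"]["domains"] = path

    timing_domains = io.read_bed_intervals(config.timing_domains_bed)
    late = [(c, s, e) for c, s, e, name in timing_domains if name == "late"]
    overlap = count_overlaps(pos, late, min_bp=config.overlap_min_bp)
    manifest["late_domain_overlap"] = asdict(overlap)

    timing = io.read_bedgraph(config.timing_bedgraph)
    try:
        corr = bin_correlation(diff, timing)
    except ValueError as exc:
        raise StageError("bin_correlation", str(exc)) from exc
    manifest["timing_correlation"] = {"r": corr.r, "n_bins": corr.n_bins}

    try:
        profile = metadomain_profile(
            late, diff, timing,
            n_inner=config.metadomain_n_inner,
            n_flank=config.metadomain_n_flank,
        )
    except ValueError as exc:
        raise StageError("metadomain", str(exc)) from exc
    path = out / "metadomain_profile.tsv"
    profile.to_frame().to_csv(path, sep="\t", index=False)
    manifest["_files"]["metadomain_profile"] = path
    manifest["metadomain_n_domains"] = profile.n_domains

    return _finish_manifest(manifest, out)


def run_h4k20me1_analysis(config: PipelineConfig) -> dict:
    """Histone-mark arm: early/late S-phase scaling and TSS/gene summaries.

    Requires ``reads['early']`` and ``reads['late']``, the chromosome
    sizes, the TSS BED and the gene BED; the non-reference condition is
    scaled to the reference (``config.scale_reference``) over the union
    of the two tracks' top-ranked bins.
    """
    config.validate_paths(["chrom_sizes", "tss_bed", "genes_bed"])
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sizes = io.read_chrom_sizes(config.chrom_sizes)
    bins = bin_genome(sizes, config.profile_bin_width, config.profile_step)

    manifest: dict = {
        "arm": "h4k20me1",
        "version": __version__,
        "parameters": asdict(config),
        "_files": {},
    }
    cond_tracks: dict[str, BinnedTrack] = {}
    for cond in ("early", "late"):
        tracks, totals = _load_condition_tracks(config, cond, bins, "coverage")
        manifest[f"replicate_pearson_{cond}"] = _replicate_correlations(tracks)
        manifest[f"total_reads_{cond}"] = totals
        cond_tracks[cond] = mean_tracks(tracks)

    ref_name = config.scale_reference
    if ref_name not in cond_tracks:
        raise StageError("scaling", f"unknown scale_reference {ref_name!r}")
    other = "early" if ref_name == "late" else "late"
    try:
        scaled, factor = scale_to_reference(
            cond_tracks[other], cond_tracks[ref_name], top_frac=config.top_frac
        )
    except ValueError as exc:
        raise StageError("scaling", str(exc)) from exc
    cond_tracks[other] = scaled
    manifest["scale_factor"] = factor
    manifest["scaled_condition"] = other
    for cond, track in cond_tracks.items():
        path = out / f"h4k20me1_{cond}.bedgraph"
        write_track(track, path)
        manifest["_files"][f"signal_{cond}"] = path

    # strand is BED column 6 when present
    df = pd.read_csv(config.tss_bed, sep="\t", header=None, comment="#")
    strands = df[5] if df.shape[1] >= 6 else ["+"] * len(df)
    anchors = AnchorSet(
        anchors=[
            (str(c), int(s), str(st))
            for c, s, st in zip(df[0], df[1], strands)
        ],
        label="tss",
    )
    for cond, track in cond_tracks.items():
        try:
            prof = anchor_aggregate(
                track, anchors,
                flank=config.anchor_flank,
                n_profile_bins=config.anchor_n_bins,
            )
        except ValueError as exc:
            raise StageError("tss_aggregate", str(exc)) from exc
        path = out / f"tss_profile_{cond}.tsv"
        pd.DataFrame(
            {"offset": prof.offsets, "mean_signal": prof.means}
        ).to_csv(path, sep="\t", index=False)
        manifest["_files"][f"tss_profile_{cond}"] = path
        manifest[f"tss_profile_n_anchors_{cond}"] = prof.n_anchors

    genes = [
        (c, s, e) for c, s, e, _ in io.read_bed_intervals(config.genes_bed)
    ]
    partition_stats = {}
    for cond, track in cond_tracks.items():
        try:
            res = genic_intergenic_partition(track, genes)
        except ValueError as exc:
            raise StageError("genic_partition", str(exc)) from exc
        partition_stats[cond] = {
            "n_genic": len(res.genic_values),
            "n_intergenic": len(res.intergenic_values),
            "genic_median": float(np.median(res.genic_values)),
            "intergenic_median": float(np.median(res.intergenic_values)),
            "rank_sum_statistic": res.statistic,
            "p_value": res.p_value,
        }
    manifest["genic_intergenic"] = partition_stats

    return _finish_manifest(manifest, out)


def run_origin_analysis(config: PipelineConfig) -> dict:
    """Origin-activity arm: condition correlation matrix and origin profile.

    Requires at least two conditions in ``config.reads`` plus the
    chromosome sizes and the origin BED.
    """
    config.validate_paths(["chrom_sizes", "origins_bed"])
    if len(config.reads) < 2:
        raise StageError("config", "need at least 2 BrdU conditions")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sizes = io.read_chrom_sizes(config.chrom_sizes)
    bins = bin_genome(sizes, config.profile_bin_width, config.profile_step)

    manifest: dict = {
        "arm": "origins",
        "version": __version__,
        "parameters": asdict(config),
        "_files": {},
    }
    labels, tracks = [], []
    for cond in config.reads:
        reps, totals = _load_condition_tracks(config, cond, bins, "coverage")
        manifest[f"total_reads_{cond}"] = totals
        mean = mean_tracks(reps)
        labels.append(cond)
        tracks.append(mean)
        path = out / f"brdu_{cond}.bedgraph"
        write_track(mean, path)
        manifest["_files"][f"signal_{cond}"] = path

    try:
        mat = correlation_matrix(tracks, labels)
    except ValueError as exc:
        raise StageError("correlation_matrix", str(exc)) from exc
    path = out / "correlation_matrix.tsv"
    mat.to_csv(path, sep="\t")
    manifest["_files"]["correlation_matrix"] = path
    manifest["correlation_matrix"] = {
        "labels": labels,
        "values": mat.to_numpy().tolist(),
    }

    ori = io.read_bed_intervals(config.origins_bed)
    anchors = AnchorSet(
        anchors=[(c, s, "+") for c, s, _, _ in ori], label="origins"
    )
    for cond, track in zip(labels, tracks):
        try:
            prof = anchor_aggregate(
                track, anchors,
                flank=config.anchor_flank,
                n_profile_bins=config.anchor_n_bins,
            )
        except ValueError as exc:
            raise StageError("origin_aggregate", str(exc)) from exc
        path = out / f"origin_profile_{cond}.tsv"
        pd.DataFrame(
            {"offset": prof.offsets, "mean_signal": prof.means}
        ).to_csv(path, sep="\t", index=False)
        manifest["_files"][f"origin_profile_{cond}"] = path

    return _finish_manifest(manifest, out)
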