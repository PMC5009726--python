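"""Synthetic genomes and simulated ChIP/BrdU-seq read sets.

Every downstream stage of the pipeline is testable without external data
because this module generates small multi-chromosome genomes with planted
replication-timing domains, TSS and origin annotations, and then draws
aligned-read intervals from a piecewise-constant enrichment intensity
over that genome.  The planted structure is retained as ground truth so
segmentation and overlap analyses can be scored exactly.

Emulated signal classes
-----------------------
* damage mark (γ-H2A.v-type): uniform background in the control,
  multiplicative enrichment inside late-replicating domains in the
  depleted condition;
* S-phase histone mark (H4K20me1-type): TSS-peaked signal, with the
  late-S sample's background elevated relative to its peaks;
* origin activity (BrdU under HU arrest): signal peaked in fixed windows
  around replication origins.

Reads are fixed-length fragments placed by their midpoint, which makes
expected bin counts exactly proportional to the configured intensity.
Sequencing error, mappability and GC bias, and read duplication are not
modeled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io
from .coverage import BinnedTrack, bin_genome
from .io import ReadSet

__all__ = [
    "SyntheticGenome",
    "EnrichmentModel",
    "make_genome",
    "make_timing_track",
    "simulate_chip_reads",
    "nucleosome_dimethyl_fraction",
    "write_fixture_bundle",
    "default_fixture",
]

EARLY, LATE = "early", "late"


@dataclass
class SyntheticGenome:
    """A small genome with known timing-domain, TSS and origin ground truth.

    ``timing_domains`` tile each chromosome exactly: non-overlapping,
    adjacent, covering [0, length), alternating early/late classes.
    """

    chrom_sizes: dict[str, int]
    timing_domains: list[tuple[str, int, int, str]]
    tss_sites: list[tuple[str, int, str]]
    origin_sites: list[tuple[str, int]]
    seed: int

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_sizes.items():
            doms = [d for d in self.timing_domains if d[0] == chrom]
            pos = 0
            for _, start, end, cls in doms:
                if start != pos or end <= start or cls not in (EARLY, LATE):
                    raise ValueError(
                        f"timing domains do not tile {chrom}: "
                        f"expected start {pos}, got [{start}, {end}) {cls}"
                    )
                pos = end
            if pos != length:
                raise ValueError(
                    f"timing domains do not cover {chrom}: end at {pos}, "
                    f"length {length}"
                )
        for chrom, p, _ in self.tss_sites:
            if not 0 <= p < self.chrom_sizes[chrom]:
                raise ValueError(f"TSS at {chrom}:{p} outside chromosome")
        for chrom, p in self.origin_sites:
            if not 0 <= p < self.chrom_sizes[chrom]:
                raise ValueError(f"origin at {chrom}:{p} outside chromosome")

    def late_domains(self) -> list[tuple[str, int, int]]:
        return [
            (c, s, e) for c, s, e, cls in self.timing_domains if cls == LATE
        ]


@dataclass
class EnrichmentModel:
    """Multiplicative piecewise-constant read-sampling intensity.

    The local intensity at a position is ``background_rate *
    global_multiplier``, further multiplied by ``late_domain_multiplier``
    inside late timing domains, ``tss_peak_multiplier`` within
    ``tss_peak_halfwidth`` bp of any TSS, and ``origin_peak_multiplier``
    within ``origin_peak_halfwidth`` bp of any origin (each feature-class
    factor applied at most once, not stacked per feature copy).
    """

    background_rate: float = 1.0
    late_domain_multiplier: float = 1.0
    tss_peak_multiplier: float = 1.0
    tss_peak_halfwidth: int = 500
    origin_peak_multiplier: float = 1.0
    origin_peak_halfwidth: int = 1000
    global_multiplier: float = 1.0
    fragment_length: int = 200

    def __post_init__(self) -> None:
        for name in (
            "background_rate", "late_domain_multiplier",
            "tss_peak_multiplier", "origin_peak_multiplier",
            "global_multiplier",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")


def make_genome(
    n_chrom: int,
    chrom_length: int,
    n_late_domains_per_chrom: int,
    late_domain_length_range: tuple[int, int] = (200_000, 400_000),
    n_tss: int = 0,
    n_origins: int = 0,
    seed: int = 0,
) -> SyntheticGenome:
    """Generate a genome with randomly placed late-replicating domains.

    Late-domain lengths are drawn uniformly from the given range and
    placed without overlap, separated by at least 1 bp of early sequence
    (so early/late domains strictly alternate and tile the chromosome).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = late_domain_length_range
    sizes = {f"chr{i + 1}": chrom_length for i in range(n_chrom)}
    domains: list[tuple[str, int, int, str]] = []
    for chrom in sizes:
        n = n_late_domains_per_chrom
        if n == 0:
            domains.append((chrom, 0, chrom_length, EARLY))
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        free = chrom_length - int(lengths.sum()) - (n + 1)
        if free < 0:
            raise ValueError(
                f"cannot place {n} late domains of {lo}-{hi} bp on {chrom} "
                f"({chrom_length} bp): footprint too large"
            )
        gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1))) + 1
        pos = 0
        for i in range(n):
            early_end = pos + int(gaps[i])
            domains.append((chrom, pos, early_end, EARLY))
            late_end = early_end + int(lengths[i])
            domains.append((chrom, early_end, late_end, LATE))
            pos = late_end
        domains.append((chrom, pos, chrom_length, EARLY))
    chrom_names = list(sizes)
    tss = []
    for _ in range(n_tss):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(sizes[chrom]))
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append((chrom, pos, strand))
    origins = []
    for _ in range(n_origins):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        origins.append((chrom, int(rng.integers(sizes[chrom]))))
    return SyntheticGenome(
        chrom_sizes=sizes,
        timing_domains=domains,
        tss_sites=sorted(tss),
        origin_sites=sorted(origins),
        seed=seed,
    )


def make_timing_track(
    genome: SyntheticGenome,
    bin_width: int = 5000,
    smooth_halfwidth: int = 0,
) -> BinnedTrack:
    """Two-level replication-timing track on non-overlapping bins.

    A bin scores +1 when its midpoint lies in an early domain and -1 in a
    late domain — higher value means earlier replication.  An optional
    box smoothing over ``smooth_halfwidth`` bp each side produces a
    softer profile; it defaults off because the analysis only needs the
    sign structure and domain boundaries.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    bins = bin_genome(genome.chrom_sizes, bin_width, bin_width)
    late = {}
    for chrom, start, end in genome.late_domains():
        late.setdefault(chrom, []).append((start, end))
    values = np.ones(len(bins))
    for i, b in enumerate(bins):
        mid = (b.start + b.end) // 2
        for s, e in late.get(b.chrom, ()):
            if s <= mid < e:
                values[i] = -1.0
                break
    track = BinnedTrack(bins, values, bin_width, bin_width, "timing")
    if smooth_halfwidth > 0:
        k = smooth_halfwidth // bin_width
        if k > 0:
            smoothed = np.empty(len(track))
            pos = 0
            kernel = np.ones(2 * k + 1) / (2 * k + 1)
            for _, (_, _, v) in track.by_chrom().items():
                padded = np.pad(v, k, mode="edge")
                smoothed[pos : pos + len(v)] = np.convolve(
                    padded, kernel, mode="valid"
                )
                pos += len(v)
            track = track.with_values(smoothed, "timing")
    return track


def _intensity_segments(
    genome: SyntheticGenome, model: EnrichmentModel
) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    """Elementary constant-intensity segments and their intensities."""
    segments: list[tuple[str, int, int]] = []
    intensities: list[float] = []
    tss_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, p, _ in genome.tss_sites:
        hw = model.tss_peak_halfwidth
        tss_by_chrom.setdefault(chrom, []).append(
            (max(0, p - hw), min(genome.chrom_sizes[chrom], p + hw))
        )
    ori_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, p in genome.origin_sites:
        hw = model.origin_peak_halfwidth
        ori_by_chrom.setdefault(chrom, []).append(
            (max(0, p - hw), min(genome.chrom_sizes[chrom], p + hw))
        )
    late_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in genome.late_domains():
        late_by_chrom.setdefault(chrom, []).append((s, e))

    def _member(windows: list[tuple[int, int]], pos: float) -> bool:
        return any(s <= pos < e for s, e in windows)

    for chrom, length in genome.chrom_sizes.items():
        breaks = {0, length}
        for coll in (tss_by_chrom, ori_by_chrom, late_by_chrom):
            for s, e in coll.get(chrom, ()):
                breaks.update((s, e))
        edges = sorted(breaks)
        for a, b in zip(edges[:-1], edges[1:]):
            mid = (a + b) / 2
            inten = model.background_rate * model.global_multiplier
            if _member(late_by_chrom.get(chrom, []), mid):
                inten *= model.late_domain_multiplier
            if _member(tss_by_chrom.get(chrom, []), mid):
                inten *= model.tss_peak_multiplier
            if _member(ori_by_chrom.get(chrom, []), mid):
                inten *= model.origin_peak_multiplier
            segments.append((chrom, a, b))
            intensities.append(inten)
    return segments, np.asarray(intensities)


def simulate_chip_reads(
    genome: SyntheticGenome,
    model: EnrichmentModel,
    n_reads: int,
    seed: int = 0,
    condition_label: str = "",
) -> ReadSet:
    """Draw fixed-length read intervals from the enrichment intensity.

    Read midpoints are sampled from a piecewise-constant density
    proportional to ``background_rate`` times the applicable multipliers;
    exactly ``n_reads`` records are produced, strands assigned uniformly.
    Fragments are shifted inward at chromosome edges so every record fits
    within its chromosome at the full fragment length.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads == 0:
        return ReadSet(records=[], condition_label=condition_label)
    segments, intensities = _intensity_segments(genome, model)
    lengths = np.array([b - a for _, a, b in segments], dtype=float)
    weights = intensities * lengths
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            "all enrichment multipliers are zero: no valid sampling density"
        )
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, weights / total)
    frag = model.fragment_length
    records: list[tuple[str, int, int, str]] = []
    for (chrom, a, b), k in zip(segments, counts):
        if k == 0:
            continue
        mids = a + rng.random(k) * (b - a)
        starts = np.clip(
            np.floor(mids).astype(np.int64) - frag // 2,
            0,
            max(0, genome.chrom_sizes[chrom] - frag),
        )
        strands = rng.random(k) < 0.5
        for s, plus in zip(starts, strands):
            records.append((chrom, int(s), int(s) + frag, "+" if plus else "-"))
    return ReadSet(records=records, condition_label=condition_label)


def nucleosome_dimethyl_fraction(p_me2_per_copy: float) -> float:
    """Fraction of nucleosomes with at least one H4K20me2-marked H4 copy.

    A nucleosome carries two H4 molecules; if each is independently
    dimethylated with probability p, the chance that at least one copy is
    marked is 1 - (1 - p)^2 (80% per copy implies 96% of nucleosomes).
    """
    if not 0 <= p_me2_per_copy <= 1:
        raise ValueError("p_me2_per_copy must be a probability in [0, 1]")
    return 1.0 - (1.0 - p_me2_per_copy) ** 2


def write_fixture_bundle(
    genome: SyntheticGenome,
    read_sets: list[ReadSet],
    out_dir: str | Path,
    timing_bin_width: int = 5000,
) -> dict[str, str]:
    """Write a genome plus read sets as a directory of plain-text files.

    Emits ``chrom.sizes``, a timing bedGraph, timing-domain / TSS /
    origin BED files, and one read BED per condition; returns a manifest
    mapping logical names to file paths.  Re-reading every file
    reproduces the in-memory objects, and two runs with identical inputs
    produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    path = out / "chrom.sizes"
    io.write_chrom_sizes(genome.chrom_sizes, path)
    manifest["chrom_sizes"] = str(path)

    path = out / "timing_domains.bed"
    io.write_bed_intervals(
        [(c, s, e, cls) for c, s, e, cls in genome.timing_domains], path
    )
    manifest["timing_domains"] = str(path)

    from .coverage import write_track

    path = out / "timing.bedgraph"
    write_track(make_timing_track(genome, timing_bin_width), path)
    manifest["timing"] = str(path)

    path = out / "tss.bed"
    io.write_bed_intervals(
        [(c, p, p + 1, "tss", 0, st) for c, p, st in genome.tss_sites], path
    )
    manifest["tss"] = str(path)

    path = out / "origins.bed"
    io.write_bed_intervals(
        [(c, p, p + 1, "origin") for c, p in genome.origin_sites], path
    )
    manifest["origins"] = str(path)

    for rs in read_sets:
        if not rs.condition_label:
            raise ValueError("every ReadSet needs a condition_label")
        path = out / f"reads_{rs.condition_label}.bed"
        io.write_reads_bed(rs, path)
        manifest[f"reads:{rs.condition_label}"] = str(path)
    return manifest


# -- the default study conditions -------------------------------------------

DEFAULT_GENOME_KW = dict(
    n_chrom=2,
    chrom_length=10_000_000,
    n_late_domains_per_chrom=5,
    late_domain_length_range=(200_000, 400_000),
    n_tss=600,
    n_origins=150,
)

DAMAGE_ENRICHMENT = 4.0       # late-domain fold enrichment after depletion
TSS_ENRICHMENT = 8.0          # TSS peak over background, early-S mark
LATE_S_PEAK_TO_BG = 8.0 / 3.0  # late-S: background elevated ~3x vs peaks
ORIGIN_ENRICHMENT = 6.0       # BrdU peak over background at origins
DEFAULT_READS_PER_REPLICATE = 200_000


def default_fixture(
    out_dir: str | Path,
    seed: int = 11,
    damage_enrichment: float = DAMAGE_ENRICHMENT,
    n_reads: int = DEFAULT_READS_PER_REPLICATE,
    n_replicates: int = 2,
    with_h4k20me1: bool = True,
    with_origins: bool = True,
) -> tuple[SyntheticGenome, dict[str, str]]:
    """Generate and write the standard synthetic dataset for all three arms.

    Two 10 Mb chromosomes, five late domains of 200-400 kb each; damage
    duplicates for control and depleted conditions, optionally early/late
    S-phase histone-mark duplicates and two BrdU conditions.  All seeds
    derive deterministically from ``seed``.
    """
    genome = make_genome(seed=seed, **DEFAULT_GENOME_KW)
    read_sets: list[ReadSet] = []

    def sub_seed(tag: str) -> int:
        h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)

    control = EnrichmentModel()
    depleted = EnrichmentModel(late_domain_multiplier=damage_enrichment)
    for rep in range(1, n_replicates + 1):
        read_sets.append(
            simulate_chip_reads(
                genome, control, n_reads, sub_seed(f"ctl{rep}"),
                condition_label=f"gh2av_control_rep{rep}",
            )
        )
        read_sets.append(
            simulate_chip_reads(
                genome, depleted, n_reads, sub_seed(f"dep{rep}"),
                condition_label=f"gh2av_depleted_rep{rep}",
            )
        )
    if with_h4k20me1:
        early_s = EnrichmentModel(tss_peak_multiplier=TSS_ENRICHMENT)
        late_s = EnrichmentModel(tss_peak_multiplier=LATE_S_PEAK_TO_BG)
        for rep in range(1, n_replicates + 1):
            read_sets.append(
                simulate_chip_reads(
                    genome, early_s, n_reads, sub_seed(f"earlyS{rep}"),
                    condition_label=f"h4k20me1_earlyS_rep{rep}",
                )
            )
            read_sets.append(
                simulate_chip_reads(
                    genome, late_s, n_reads, sub_seed(f"lateS{rep}"),
                    condition_label=f"h4k20me1_lateS_rep{rep}",
                )
            )
    if with_origins:
        brdu = EnrichmentModel(origin_peak_multiplier=ORIGIN_ENRICHMENT)
        for i, label in enumerate(("brdu_hu_a", "brdu_hu_b")):
            read_sets.append(
                simulate_chip_reads(
                    genome, brdu, n_reads, sub_seed(f"brdu{i}"),
                    condition_label=label,
                )
            )
    manifest = write_fixture_bundle(genome, read_sets, out_dir)
    # simple gene models for the genic/intergenic partition: each TSS
    # opens a 2 kb gene body in its strand's direction
    genes = []
    for chrom, pos, strand in genome.tss_sites:
        length = genome.chrom_sizes[chrom]
        if strand == "+":
            s, e = pos, min(length, pos + 2000)
        else:
            s, e = max(0, pos - 2000), pos + 1
        genes.append((chrom, s, e, "gene"))
    gene_path = Path(out_dir) / "genes.bed"
    io.write_bed_intervals(genes, gene_path)
    manifest["genes"] = str(gene_path)
    return genome, manifest
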