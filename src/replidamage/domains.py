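"""Integration of called damage domains with replication timing.

Three analyses connect the segmentation output to replication-timing
data: reciprocal overlap accounting between damage domains and
late-replicating domains, the per-bin Pearson correlation between the
log2-difference track and the timing profile, and a metadomain profile
that rescales every late domain to a fixed number of inner bins plus
equal-width flanks and averages signal and timing across domains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .coverage import BinnedTrack, interval_weighted_means
from .hmm import Domain

__all__ = [
    "DomainOverlapSummary",
    "MetadomainProfile",
    "BinCorrelation",
    "count_overlaps",
    "bin_correlation",
    "metadomain_profile",
]

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]


def _as_intervals(items: Sequence) -> list[Interval]:
    out = []
    for it in items:
        if isinstance(it, Domain):
            out.append((it.chrom, it.start, it.end))
        else:
            chrom, start, end = it[0], int(it[1]), int(it[2])
            if end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            out.append((chrom, start, end))
    return out


@dataclass
class DomainOverlapSummary:
    """Reciprocal any-overlap accounting between two domain sets."""

    n_query: int
    n_reference: int
    n_query_hit: int       # query domains overlapping >= 1 reference domain
    n_reference_hit: int   # reference domains overlapping >= 1 query domain


def count_overlaps(
    query: Sequence,
    reference: Sequence,
    min_bp: int = 1,
) -> DomainOverlapSummary:
    """Count, on each side, domains that overlap the other set.

    Overlap means a shared span of at least ``min_bp`` base pairs on the
    same chromosome; each domain is counted once regardless of how many
    partners it touches.  The default ``min_bp=1`` is the weakest
    any-overlap reading.
    """
    q = _as_intervals(query)
    r = _as_intervals(reference)
    trees: dict[str, IntervalTree] = {}
    for idx, (chrom, start, end) in enumerate(r):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, idx)
    q_hit = 0
    r_hit: set[int] = set()
    for chrom, start, end in q:
        tree = trees.get(chrom)
        if tree is None:
            continue
        hit_any = False
        for iv in tree.overlap(start, end):
            if min(iv.end, end) - max(iv.begin, start) >= min_bp:
                hit_any = True
                r_hit.add(iv.data)
        q_hit += hit_any
    return DomainOverlapSummary(
        n_query=len(q),
        n_reference=len(r),
        n_query_hit=q_hit,
        n_reference_hit=len(r_hit),
    )


class BinCorrelation(NamedTuple):
    r: float
    n_bins: int


def _interval_arrays(
    timing: "BinnedTrack | pd.DataFrame | Sequence",
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends, values) from a track, DataFrame of
    bedGraph records, or a sequence of (chrom, start, end, value)."""
    if isinstance(timing, BinnedTrack):
        return timing.by_chrom()
    if isinstance(timing, pd.DataFrame):
        rows = timing[["chrom", "start", "end", "value"]].itertuples(index=False)
    else:
        rows = timing
    acc: dict[str, list[list]] = {}
    for chrom, start, end, value in rows:
        acc.setdefault(str(chrom), [[], [], []])
        acc[str(chrom)][0].append(int(start))
        acc[str(chrom)][1].append(int(end))
        acc[str(chrom)][2].append(float(value))
    out = {}
    for chrom, (s, e, v) in acc.items():
        s, e, v = map(np.asarray, (s, e, v))
        order = np.argsort(s, kind="stable")
        out[chrom] = (s[order], e[order], v[order].astype(float))
    return out


def resample_to_bins(timing, track: BinnedTrack) -> np.ndarray:
    """Length-weighted mean of ``timing`` values over each bin of ``track``.

    Bins with no timing coverage get NaN.
    """
    arrays = _interval_arrays(timing)
    out = np.full(len(track), np.nan)
    pos = 0
    for chrom, (bs, be, _) in track.by_chrom().items():
        n = len(bs)
        if chrom in arrays:
            ts, te, tv = arrays[chrom]
            out[pos : pos + n] = interval_weighted_means(
                ts, te, tv, list(zip(bs, be))
            )
        pos += n
    return out


def bin_correlation(diff: BinnedTrack, timing) -> BinCorrelation:
    """Pearson correlation between a differential track and timing, per bin.

    The timing profile is resampled onto the differential track's exact
    bins by length-weighted mean; bins without timing data are excluded
    pairwise.  Returns the correlation and the number of bin pairs used.
    """
    t = resample_to_bins(timing, diff)
    mask = np.isfinite(t) & np.isfinite(diff.values)
    x, y = diff.values[mask], t[mask]
    if len(x) < 2:
        raise ValueError("fewer than 2 paired bins with timing data")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    r = float(stats.pearsonr(x, y).statistic)
    return BinCorrelation(r=r, n_bins=int(mask.sum()))


@dataclass
class MetadomainProfile:
    """Average signal over domains rescaled to a common coordinate.

    Positions are meta-bin centers in domain-length units: the domain
    spans [0, 1]; flanks extend to -0.5 and 1.5.
    """

    positions: np.ndarray      # 100 relative coordinates
    signal_means: np.ndarray
    timing_means: np.ndarray
    n_domains: int
    n_inner: int = 50
    n_flank: int = 25
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_index": np.arange(len(self.positions)),
                "relative_coordinate": self.positions,
                "signal_mean": self.signal_means,
                "timing_mean": self.timing_means,
                "n_domains": self.n_domains,
            }
        )


def metadomain_profile(
    domains: Sequence,
    signal: BinnedTrack,
    timing,
    n_inner: int = 50,
    n_flank: int = 25,
) -> MetadomainProfile:
    """Rescale each domain to ``n_inner`` meta-bins plus flanks and average.

    Each domain of length L is divided into ``n_inner`` inner meta-bins of
    width L / n_inner (fractional widths allowed); ``n_flank`` meta-bins of
    the same width extend outward on each side.  A meta-bin's value is the
    length-weighted mean of the track bins it overlaps; meta-bins beyond
    chromosome ends contribute no value.  Per-position means are taken
    across domains over the finite values.  Domains shorter than
    ``n_inner`` bp are skipped with a warning.
    """
    ivs = _as_intervals(domains)
    sig_arr = signal.by_chrom()
    tim_arr = _interval_arrays(timing)
    n_pos = n_flank + n_inner + n_flank
    sig_rows, tim_rows = [], []
    skipped = 0
    for chrom, start, end in ivs:
        length = end - start
        if length < n_inner:
            logger.warning(
                "domain %s:%d-%d shorter than %d bp; skipped",
                chrom, start, end, n_inner,
            )
            skipped += 1
            continue
        w = length / n_inner
        edges = start + (np.arange(n_pos + 1) - n_flank) * w
        queries = list(zip(edges[:-1], edges[1:]))
        if chrom in sig_arr:
            ss, se, sv = sig_arr[chrom]
            sig_rows.append(interval_weighted_means(ss, se, sv, queries))
        else:
            sig_rows.append(np.full(n_pos, np.nan))
        if chrom in tim_arr:
            ts, te, tv = tim_arr[chrom]
            tim_rows.append(interval_weighted_means(ts, te, tv, queries))
        else:
            tim_rows.append(np.full(n_pos, np.nan))
    if not sig_rows:
        raise ValueError("no domain long enough to profile")
    positions = (np.arange(n_pos) - n_flank + 0.5) / n_inner
    with warnings.catch_warnings():
        # positions with no finite value in any domain are legitimately NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        sig_means = np.nanmean(np.vstack(sig_rows), axis=0)
        tim_means = np.nanmean(np.vstack(tim_rows), axis=0)
    return MetadomainProfile(
        positions=positions,
        signal_means=sig_means,
        timing_means=tim_means,
        n_domains=len(sig_rows),
        n_inner=n_inner,
        n_flank=n_flank,
        n_skipped=skipped,
    )
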