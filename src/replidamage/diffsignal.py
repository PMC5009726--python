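"""Cross-sample normalization and the differential enrichment statistic.

Two tracks from different samples are put on a common scale by matching
their mean signal over the union of each track's top-ranked bins (a
rank-based stand-in for "top of detected peaks" scaling, reproducible and
parameter-free beyond the fraction).  The differential statistic is a
pseudocounted log2 ratio:

    log2_difference = log2(treatment + 1) - log2(control + 1)

computed per bin on RPKM tracks; a positive value means enrichment in the
treatment condition.  The pseudocount of exactly 1 RPKM keeps every output
finite for non-negative input.
"""

from __future__ import annotations

import math

import numpy as np

from .coverage import BinnedTrack

__all__ = ["top_bin_set", "scale_to_reference", "log2_difference"]


def top_bin_set(track: BinnedTrack, top_frac: float) -> set[int]:
    """Indices of the ``ceil(top_frac * n_bins)`` highest-valued bins.

    Ties are broken by genomic order: the earlier bin wins.
    """
    if not (0 < top_frac < 1):
        raise ValueError("top_frac must be in (0, 1)")
    n = len(track)
    if n == 0:
        raise ValueError("empty track")
    k = math.ceil(top_frac * n)
    # stable sort of negated values keeps earlier bins first among ties
    order = np.argsort(-track.values, kind="stable")
    return set(int(i) for i in order[:k])


def scale_to_reference(
    sample: BinnedTrack,
    reference: BinnedTrack,
    top_frac: float = 0.05,
) -> tuple[BinnedTrack, float]:
    """Rescale ``sample`` so its top-enrichment level matches ``reference``.

    Let U be the union of the two tracks' top-bin sets; the scale factor
    is ``mean(reference over U) / mean(sample over U)`` and every sample
    value is multiplied by it.  Returns the scaled track (units
    ``scaled_rpkm``) and the factor.
    """
    if not sample.same_binning(reference):
        raise ValueError("sample and reference are not on identical bins")
    union = sorted(top_bin_set(sample, top_frac) | top_bin_set(reference, top_frac))
    idx = np.asarray(union, dtype=int)
    ref_mean = float(np.mean(reference.values[idx]))
    sample_mean = float(np.mean(sample.values[idx]))
    if ref_mean <= 0 or sample_mean <= 0:
        raise ValueError(
            "zero mean over the top-bin union; cannot derive a scale factor"
        )
    factor = ref_mean / sample_mean
    return sample.with_values(sample.values * factor, "scaled_rpkm"), factor


def log2_difference(
    treatment: BinnedTrack, control: BinnedTrack
) -> BinnedTrack:
    """Per-bin ``log2(t + 1) - log2(c + 1)`` differential track."""
    if not treatment.same_binning(control):
        raise ValueError("treatment and control are not on identical bins")
    for t in (treatment, control):
        if t.units not in ("rpkm", "scaled_rpkm"):
            raise ValueError(f"expected an RPKM track, got units {t.units!r}")
        if np.any(t.values < 0):
            raise ValueError("negative value in an RPKM track")
    values = np.log2(treatment.values + 1.0) - np.log2(control.values + 1.0)
    return treatment.with_values(values, "log2_difference")
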