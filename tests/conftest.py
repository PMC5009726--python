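import numpy as np
import pytest

from replidamage.coverage import BinnedTrack, bin_genome
from replidamage.synthetic import SyntheticGenome, make_genome


@pytest.fixture(scope="session")
def small_genome() -> SyntheticGenome:
    """Two 1 Mb chromosomes with two planted late domains each."""
    return make_genome(
        n_chrom=2,
        chrom_length=1_000_000,
        n_late_domains_per_chrom=2,
        late_domain_length_range=(100_000, 150_000),
        n_tss=40,
        n_origins=20,
        seed=7,
    )


@pytest.fixture
def half_late_genome() -> SyntheticGenome:
    """One 1 Mb chromosome, early in the first half, late in the second."""
    return SyntheticGenome(
        chrom_sizes={"chr1": 1_000_000},
        timing_domains=[
            ("chr1", 0, 500_000, "early"),
            ("chr1", 500_000, 1_000_000, "late"),
        ],
        tss_sites=[],
        origin_sites=[],
        seed=0,
    )


def make_track(values, chrom="c", width=5000, units="rpkm") -> BinnedTrack:
    """A one-chromosome non-overlapping track with the given values."""
    values = np.asarray(values, dtype=float)
    bins = bin_genome({chrom: width * len(values)}, width, width)
    return BinnedTrack(bins, values, width, width, units)
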