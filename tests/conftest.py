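import numpy as np
import pytest

from cnahier.bins import GenomeBins
from cnahier.rd import RDProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_profile():
    """10k-bin CN-neutral profile at 2x coverage, Poisson noise."""
    rng = np.random.default_rng(7)
    gb = GenomeBins("chrT", 10_000_000, 1000)
    counts = rng.poisson(2.0 * 1000, size=gb.n_bins)
    return RDProfile(gb, counts / 1000)


def make_profile(rd_values, chromosome="chrT", bin_size=1000):
    rd_values = np.asarray(rd_values, dtype=float)
    gb = GenomeBins(chromosome, rd_values.size * bin_size, bin_size)
    return RDProfile(gb, rd_values)
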