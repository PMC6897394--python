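import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_intervals(rng, n_max=50, chrom_len=10_000, chroms=("chr1", "chr2")):
    """Small random interval list for oracle comparisons."""
    from epidomains.intervals import GenomicInterval

    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, chrom_len - 1))
        end = int(rng.integers(start + 1, min(chrom_len, start + 500) + 1))
        out.append(GenomicInterval(chrom, start, end))
    return out
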