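import numpy as np
import pandas as pd
import pytest

from promtarget.core import PromoterModel, TilingProbe


@pytest.fixture
def toy_promoter():
    """Single promoter on + strand with TSS at 10000."""
    return PromoterModel.from_tss("gA", "chr1", "+", 10_000)


def make_probe_row(probe_id, chrom, mid, length=60, promoter_id=None, is_control=False):
    start = mid - length // 2
    return TilingProbe(probe_id, chrom, start, start + length, promoter_id, is_control)


@pytest.fixture
def five_probe_promoter():
    """The 5-probe toy: midpoints 0..400 step 100 inside one promoter.

    TSS placed at 400 so the promoter interval [tss-2200, tss+500) covers
    all probe midpoints.
    """
    prom = PromoterModel.from_tss("gT", "chr1", "+", 400)
    probes = [make_probe_row(f"p{i}", "chr1", i * 100, 60, "gT") for i in range(5)]
    values = pd.Series([1.0, 2.0, 9.0, 2.0, 1.0], index=[p.probe_id for p in probes])
    return prom, probes, values


def random_probe_track(rng, n, spacing_low=60, spacing_high=160, chrom="chr1"):
    """Irregularly spaced sorted probes on one chromosome with random values."""
    gaps = rng.integers(spacing_low, spacing_high, size=n)
    mids = np.cumsum(gaps) + 1000
    probes = [make_probe_row(f"r{i}", chrom, int(m), 60, "gX") for i, m in enumerate(mids)]
    values = pd.Series(rng.normal(size=n), index=[p.probe_id for p in probes])
    return probes, values
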