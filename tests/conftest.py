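import numpy as np
import pandas as pd
import pytest

from dmrscan import (
    GenomicInterval,
    PipelineConfig,
    Probe,
    ProbeLayout,
    PScoreTrack,
    SignalTrack,
)


@pytest.fixture
def config():
    return PipelineConfig()


def make_layout(spacing=100, n=100, chrom="chr1", start=0, probe_len=50):
    """Evenly spaced probe layout on one chromosome."""
    return ProbeLayout(
        Probe(f"{chrom}_P{i:04d}", GenomicInterval(chrom, start + i * spacing,
                                                   start + i * spacing + probe_len))
        for i in range(n)
    )


def make_pscore_track(layout, pscores, sample_id="s"):
    return PScoreTrack(sample_id, pd.Series(list(pscores), index=layout.probe_ids))


def make_signal_track(layout, values, sample_id="s", scaled=True):
    return SignalTrack(sample_id, pd.Series(list(values), index=layout.probe_ids),
                       scaled=scaled)


@pytest.fixture
def layout100():
    return make_layout()


def per_base_mask(intervals, size, chrom=None):
    """Boolean-mask oracle over [0, size)."""
    m = np.zeros(size, dtype=bool)
    for iv in intervals:
        if chrom is None or iv.chrom == chrom:
            m[iv.start : iv.end] = True
    return m
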