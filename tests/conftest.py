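import numpy as np
import pytest

from poolinv.io_formats import BreakpointInterval, MarkerSet
from poolinv.synth import SynthPanelConfig, make_panel


@pytest.fixture
def interval_2l() -> BreakpointInterval:
    return BreakpointInterval(name="In(2L)t", chrom="2L", start=500_000, end=1_500_000)


@pytest.fixture
def planted_panel(interval_2l):
    """Panel of 20 standard + 10 inverted chromosomes, 30 planted markers."""
    cfg = SynthPanelConfig(
        arm_length=2_000_000,
        n_standard=20,
        n_inverted=10,
        interval=interval_2l,
        n_planted=30,
        shared_snps=500,
        seed=42,
    )
    return make_panel(cfg, inversion="In(2L)t")


@pytest.fixture
def planted_markers(planted_panel) -> MarkerSet:
    _, truth = planted_panel
    return MarkerSet(truth.planted)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
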