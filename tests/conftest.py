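import numpy as np
import pytest

from rohaudit.config import RunConfig
from rohaudit.core import GenomicInterval, MarkerMap
from rohaudit.pipeline import run_pipeline
from rohaudit.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study: planted islands of every label, fixed seed."""
    return simulate_dataset(SimConfig(seed=11, with_intensities=False))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline result on the default synthetic study."""
    config = RunConfig(seed=11)
    return run_pipeline(
        default_sim.dataset,
        default_sim.calls_a,
        default_sim.calls_b,
        default_sim.haplotypes,
        config,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_map(positions, chrom="1"):
    """Small helper: a MarkerMap on one chromosome from 1-based positions."""
    return MarkerMap([chrom] * len(positions), [f"m{i}" for i in range(len(positions))], positions)


@pytest.fixture()
def simple_map():
    return make_map([1000 * (i + 1) for i in range(100)])


def iv(chrom, start, end):
    return GenomicInterval(str(chrom), start, end)
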