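import numpy as np
import pytest
from hypothesis import settings

from epitoc import CpGMap, EpialleleProfile, Region, RunConfig, SimConfig, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_study():
    """30-bin two-group study with injected TOC and mDMR events."""
    return simulate_study(
        SimConfig(n_bins=30, toc_fraction=0.2, dmr_fraction=0.2, seed=7)
    )


@pytest.fixture
def default_config():
    return RunConfig(seed=7)


def make_profile(counts: dict[str, int], start: int = 0, chrom: str = "chr1") -> EpialleleProfile:
    k = len(next(iter(counts)))
    return EpialleleProfile(
        region=Region(chrom, start, start + 100),
        k=k,
        counts=dict(counts),
        total=sum(counts.values()),
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture(scope="session")
def uniform_genome():
    """Synthetic 2-Mb chromosome with a CpG every 50 bp (uniform density)."""
    size = 2_000_000
    positions = list(range(25, size, 50))
    return CpGMap({"chrU": positions}), {"chrU": size}
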