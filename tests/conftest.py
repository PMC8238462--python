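import numpy as np
import pytest

from mslsites.intervals import Interval
from mslsites.orthomap import OrthologBlock, OrthologMap


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture()
def identity_map():
    """One block mapping chr c 0-10000 onto itself."""
    return OrthologMap(
        [OrthologBlock(Interval("c", 0, 10_000), Interval("c", 0, 10_000), "+")]
    )


@pytest.fixture()
def shifted_map():
    """cA 0-1000 -> cB 5000-6000 forward strand."""
    return OrthologMap(
        [OrthologBlock(Interval("cA", 0, 1000), Interval("cB", 5000, 6000), "+")]
    )


def brute_force_overlap(a: Interval, b: Interval) -> int:
    """Per-base set-intersection oracle, deliberately naive."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def brute_force_rule(a: Interval, b: Interval, mode: str, center=None) -> bool:
    ov = brute_force_overlap(a, b)
    if mode == "reciprocal_half":
        return ov > a.length / 2 and ov > b.length / 2
    if mode == "either_half":
        return ov > a.length / 2 or ov > b.length / 2
    if mode == "one_sided_half":
        return ov >= a.length / 2
    if mode == "center_within":
        return a.chrom == b.chrom and a.start <= center < a.end
    raise AssertionError(mode)
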