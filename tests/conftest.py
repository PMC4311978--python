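import itertools

import numpy as np
import pytest

from sirm import Adjacency, HyperParams, Partition, RegionSet, StreamlineData


def set_partitions(items):
    """Enumerate all set partitions of `items` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def partition_from_blocks(blocks, n):
    z = np.empty(n, dtype=np.int64)
    for k, block in enumerate(blocks):
        for i in block:
            z[i] = k
    return Partition(z)


def all_partitions(n):
    return [partition_from_blocks(b, n) for b in set_partitions(range(n))]


def compositions(total, parts):
    """All non-negative integer vectors of length `parts` summing to `total`."""
    for cuts in itertools.combinations_with_replacement(range(total + 1), parts - 1):
        vec = np.diff((0,) + cuts + (total,))
        yield np.array(vec, dtype=np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hp():
    return HyperParams()


@pytest.fixture
def regions3():
    return RegionSet(("amygdala", "hippocampus", "thalamus"))


@pytest.fixture
def small_streamlines():
    return StreamlineData(np.array([[0, 50, 5], [40, 0, 10], [3, 60, 0]]))


@pytest.fixture
def planted_community():
    """Three clusters of four, complete within and empty between."""
    partition = Partition(np.repeat(np.arange(3), 4))
    a = np.zeros((12, 12), dtype=np.uint8)
    for k in range(3):
        idx = np.arange(4 * k, 4 * (k + 1))
        a[np.ix_(idx, idx)] = 1
    np.fill_diagonal(a, 0)
    return partition, Adjacency(a)
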