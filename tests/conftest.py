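"""Shared fixtures: the printed toy sets, small genomes, random instances."""

import numpy as np
import pytest

from multioverlap import (
    Genome,
    GenomicRegion,
    RegionSet,
    merge_regions,
)


@pytest.fixture
def toy_genome():
    return Genome({"chr1": 1000, "chr2": 1000})


@pytest.fixture
def set_A():
    return merge_regions(RegionSet.from_iterable(
        "A", [GenomicRegion("chr1", 100, 200), GenomicRegion("chr1", 500, 550)]
    ))


@pytest.fixture
def set_B():
    return merge_regions(RegionSet.from_iterable(
        "B", [GenomicRegion("chr1", 480, 520), GenomicRegion("chr2", 100, 210)]
    ))


@pytest.fixture
def set_C():
    return merge_regions(RegionSet.from_iterable(
        "C", [GenomicRegion("chr1", 510, 520)]
    ))


def random_instance(rng: np.random.Generator, max_sets: int = 8, max_bp: int = 50_000):
    """A random small genome plus 2..max_sets merged region sets."""
    n_chroms = int(rng.integers(1, 4))
    lengths = rng.integers(2_000, max_bp // n_chroms + 1, size=n_chroms)
    genome = Genome({f"chr{i+1}": int(l) for i, l in enumerate(lengths)})
    k = int(rng.integers(2, max_sets + 1))
    sets = []
    for j in range(k):
        regions = []
        for chrom, L in genome.chrom_lengths.items():
            n = int(rng.integers(0, 12))
            for _ in range(n):
                start = int(rng.integers(0, L - 1))
                end = int(rng.integers(start + 1, min(L, start + 400) + 1))
                regions.append(GenomicRegion(chrom, start, end))
        sets.append(merge_regions(RegionSet.from_iterable(f"s{j}", regions)))
    return genome, sets
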