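"""Synthetic data generators and the per-base-pair oracle.

Everything here is a pure function of its seed.  Two generators cover the
two kinds of inputs the pipeline takes:

* :func:`gen_region_sets` builds artificial BED-style region sets with a
  controlled association structure — a query placed uniformly at random,
  references that copy a designated fraction of the query's regions (with
  optional positional jitter) and fill the rest independently, and fully
  independent negative controls.

* :func:`gen_overlap_matrix` builds a binary overlap matrix from planted
  "complexes" (itemsets) with chosen abundances, then flips each cell
  independently with a given noise rate — the standard benchmark for the
  itemset miner (complexes AB, ABCD, EF over k = 6, m ~ 1000).

:func:`brute_force_oracle` recomputes exact per-combination (S, N) by
scanning every base pair of a small genome — an independent check of the
sweep-line path, deliberately sharing no code with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import Genome, GenomicRegion, RegionSet, merge_regions
from .modl_miner import OverlapMatrix
from .overlap_core import Combination

__all__ = [
    "ReferenceSpec",
    "AssociationSpec",
    "PlantedMatrixSpec",
    "gen_region_sets",
    "gen_overlap_matrix",
    "brute_force_oracle",
]

_ORACLE_MAX_BP = 1_000_000  # memory guard: the scan allocates one int per bp


@dataclass(frozen=True)
class ReferenceSpec:
    """One reference set: fraction of query regions it copies, and jitter.

    ``overlap_fraction = 0`` makes an independent negative control.
    Jitter is an independent uniform shift in [-jitter, +jitter] bp applied
    to each copied region.
    """

    name: str
    overlap_fraction: float = 0.0
    jitter: int = 0
    n_regions: int | None = None  # defaults to the query's count

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class AssociationSpec:
    """Recipe for a family of region sets with known pairwise association."""

    genome: Genome
    n_query_regions: int = 1000
    region_length: int = 100
    references: tuple[ReferenceSpec, ...] = ()
    query_name: str = "query"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "references", tuple(self.references))


def _place_uniform(
    genome: Genome, n: int, length: int, rng: np.random.Generator
) -> list[GenomicRegion]:
    """Place n non-overlapping regions of fixed length uniformly at random.

    Chromosomes are chosen proportionally to their length; within each one,
    starts are drawn by the gap-allocation construction (uniform over
    non-overlapping layouts)."""
    chroms = list(genome.chrom_lengths)
    sizes = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(n, sizes / sizes.sum())
    out: list[GenomicRegion] = []
    for chrom, m in zip(chroms, counts):
        if m == 0:
            continue
        L = genome.chrom_lengths[chrom]
        free = L - m * length
        if free < 0:
            raise ValueError(
                f"infeasible density: {m} x {length} bp does not fit in {chrom} ({L} bp)"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=m))
        starts = cuts + np.arange(m) * length
        for s in starts:
            out.append(GenomicRegion(chrom, int(s), int(s) + length))
    return out


def gen_region_sets(
    spec: AssociationSpec,
) -> tuple[list[RegionSet], pd.DataFrame]:
    """Generate the query, its references, and the design ground truth.

    Each reference copies ``round(overlap_fraction * n)`` randomly chosen
    query regions (shifted by its jitter) and places the remainder of its
    regions independently.  Returns the merged sets (query first) and a
    table of the designed per-reference overlap fractions.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    total_needed = spec.n_query_regions * spec.region_length
    if total_needed * 2 > spec.genome.total_bp:
        raise ValueError("infeasible density: query would cover most of the genome")

    query_regions = _place_uniform(
        spec.genome, spec.n_query_regions, spec.region_length, rng
    )
    sets = [merge_regions(RegionSet.from_iterable(spec.query_name, query_regions))]
    truth_rows = []
    for ref in spec.references:
        n_ref = ref.n_regions if ref.n_regions is not None else spec.n_query_regions
        n_copied = int(round(ref.overlap_fraction * n_ref))
        n_copied = min(n_copied, len(query_regions))
        picked = rng.choice(len(query_regions), size=n_copied, replace=False)
        regions: list[GenomicRegion] = []
        for i in picked:
            q = query_regions[i]
            shift = int(rng.integers(-ref.jitter, ref.jitter + 1)) if ref.jitter else 0
            start = max(0, q.start + shift)
            end = min(spec.genome.chrom_lengths[q.chrom], q.end + shift)
            if end > start:
                regions.append(GenomicRegion(q.chrom, start, end))
        regions.extend(
            _place_uniform(spec.genome, n_ref - n_copied, spec.region_length, rng)
        )
        sets.append(merge_regions(RegionSet.from_iterable(ref.name, regions)))
        truth_rows.append(
            {
                "reference": ref.name,
                "overlap_fraction": ref.overlap_fraction,
                "jitter": ref.jitter,
                "n_regions": n_ref,
                "negative_control": ref.overlap_fraction == 0.0,
            }
        )
    return sets, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class PlantedMatrixSpec:
    """Recipe for a planted-complex binary matrix.

    The default mirrors the standard miner benchmark: complexes AB, ABCD
    and EF over k = 6 sets in comparable abundance (two of them
    overlapping in items), m = 1000 rows.
    """

    set_names: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")
    complexes: tuple[frozenset[int], ...] = (
        frozenset({0, 1}),          # AB
        frozenset({0, 1, 2, 3}),    # ABCD
        frozenset({4, 5}),          # EF
    )
    abundances: tuple[float, ...] = (0.4, 0.3, 0.3)
    m: int = 1000
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.complexes) != len(self.abundances):
            raise ValueError("one abundance per complex required")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must be in [0, 1)")
        k = len(self.set_names)
        for comp in self.complexes:
            if not comp:
                raise ValueError("empty complex")
            if max(comp) >= k:
                raise ValueError(f"complex {sorted(comp)} exceeds k={k}")


def gen_overlap_matrix(
    spec: PlantedMatrixSpec,
) -> tuple[OverlapMatrix, pd.DataFrame]:
    """Draw rows from the planted complexes, then apply bit-flip noise.

    Each row is the indicator vector of one complex chosen with the given
    abundances; every cell is then flipped independently with probability
    ``noise_rate``.  Returns the matrix and a ground-truth table with the
    realized draw counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    k = len(spec.set_names)
    indicators = np.zeros((len(spec.complexes), k), dtype=np.int8)
    for i, comp in enumerate(spec.complexes):
        indicators[i, sorted(comp)] = 1
    choices = rng.choice(len(spec.complexes), size=spec.m, p=np.asarray(spec.abundances))
    data = indicators[choices]
    if spec.noise_rate > 0:
        flips = rng.random(data.shape) < spec.noise_rate
        data = np.where(flips, 1 - data, data)
    truth = pd.DataFrame(
        {
            "complex": [
                "".join(spec.set_names[j] for j in sorted(c)) for c in spec.complexes
            ],
            "members": [tuple(sorted(c)) for c in spec.complexes],
            "abundance": spec.abundances,
            "n_rows": np.bincount(choices, minlength=len(spec.complexes)),
        }
    )
    return OverlapMatrix(data.astype(np.int8), spec.set_names), truth


def brute_force_oracle(
    sets: Sequence[RegionSet], genome: Genome
) -> dict[Combination, tuple[int, int]]:
    """Exact per-combination (S, N) by scanning every base pair.

    For each chromosome an integer bitmask array of length L marks which
    sets cover each position; runs of an identical mask with >= 2 open
    sets are tallied.  Independent of the sweep-line implementation.
    """
    if genome.total_bp > _ORACLE_MAX_BP:
        raise ValueError(
            f"genome of {genome.total_bp} bp exceeds the oracle guard of {_ORACLE_MAX_BP}"
        )
    k = len(sets)
    tallies: dict[int, tuple[int, int]] = {}
    for chrom, L in genome.chrom_lengths.items():
        cover = np.zeros(L, dtype=np.int64)
        for j, rs in enumerate(sets):
            for r in rs:
                if r.chrom == chrom:
                    cover[r.start : r.end] |= 1 << j
        popcount = np.bitwise_count(cover.astype(np.uint64))
        interesting = popcount >= 2
        if not interesting.any():
            continue
        # run-length encode the mask sequence
        change = np.nonzero(np.diff(cover))[0] + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [L]))
        for s, e in zip(starts, ends):
            mask = int(cover[s])
            if bin(mask).count("1") >= 2:
                S, N = tallies.get(mask, (0, 0))
                tallies[mask] = (S + int(e - s), N + 1)
    return {
        Combination.from_mask(mask, k): sn for mask, sn in sorted(tallies.items())
    }
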