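"""Monte Carlo null model: shuffle region sets preserving length structure.

Under the null hypothesis the sets are mutually independent, but regions
within a set are *not* assumed uniformly placed: each shuffle permutes, per
chromosome, the multiset of region lengths and — independently — the
multiset of inter-region gap lengths (including the two flanks to the
chromosome ends), then lays them out end to start.  Both multisets are
therefore conserved exactly, so the spatial texture of each set (clumpy or
regular) is carried into the null.

A chromosome with m regions has m + 1 gaps, possibly zero-length at the
ends.  Regions that become abutting after a zero-length gap is drawn
between them are fused before counting, consistent with merged-set
semantics.

Seeding uses one independent substream per (shuffle index, set index), so
results are identical for any batch size and for any processing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_model import Genome, GenomicRegion, RegionSet, merge_regions
from .overlap_core import (
    Combination,
    CountingMode,
    IntersectionMatrix,
    count_combinations,
    sweep_intersections,
)

__all__ = ["ShuffleConfig", "ShuffleSamples", "shuffle_regions", "run_monte_carlo"]


@dataclass(frozen=True)
class ShuffleConfig:
    """Monte Carlo parameters.

    100-200 shuffles are normally enough for a stable Negative Binomial
    moment fit; the default is 200.  Sets named in ``locked_set_names``
    keep their true positions in every shuffle.
    """

    n_shuffles: int = 200
    seed: int = 42
    locked_set_names: frozenset[str] = frozenset()
    batch_size: int = 50

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        object.__setattr__(self, "locked_set_names", frozenset(self.locked_set_names))


@dataclass
class ShuffleSamples:
    """Per-combination S and N arrays, one entry per shuffle.

    Combinations absent from a given shuffle contribute 0.  ``mode``
    records the counting mode used, since S values are not comparable
    across modes.
    """

    set_names: list[str]
    mode: CountingMode
    n_shuffles: int
    S: dict[Combination, np.ndarray] = field(default_factory=dict)
    N: dict[Combination, np.ndarray] = field(default_factory=dict)

    def combinations(self) -> list[Combination]:
        return list(self.S)

    def to_tsv(self, path) -> None:
        """Serialize as a long-format TSV (one row per combination/shuffle),
        the accumulator format used for superbatch merging across runs."""
        import pandas as pd

        records = []
        for comb in self.combinations():
            label = ",".join(comb.members(self.set_names))
            for i in range(self.n_shuffles):
                records.append((label, i, int(self.S[comb][i]), int(self.N[comb][i])))
        pd.DataFrame(records, columns=["combination", "shuffle", "S", "N"]).to_csv(
            path, sep="\t", index=False
        )
        with open(path, "a") as fh:
            fh.write(f"# mode={self.mode} sets={','.join(self.set_names)}\n")

    @classmethod
    def from_tsv(cls, path) -> "ShuffleSamples":
        import pandas as pd

        with open(path) as fh:
            lines = fh.read().splitlines()
        meta = lines[-1].lstrip("# ").split()
        mode = meta[0].split("=", 1)[1]
        set_names = meta[1].split("=", 1)[1].split(",")
        from io import StringIO

        df = pd.read_csv(StringIO("\n".join(lines[:-1])), sep="\t")
        n_shuffles = int(df["shuffle"].max()) + 1 if len(df) else 0
        out = cls(set_names, mode, n_shuffles)  # type: ignore[arg-type]
        for label, grp in df.groupby("combination", sort=False):
            comb = Combination(tuple(n in label.split(",") for n in set_names))
            grp = grp.sort_values("shuffle")
            out.S[comb] = grp["S"].to_numpy(dtype=np.int64)
            out.N[comb] = grp["N"].to_numpy(dtype=np.int64)
        return out


def _substream(seed: int, shuffle_index: int, set_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, shuffle_index, set_index)))


def shuffle_regions(rs: RegionSet, genome: Genome, rng: np.random.Generator) -> RegionSet:
    """One null draw of a region set.

    Per chromosome, region lengths and gap lengths are permuted as two
    separate series and re-laid from the chromosome start.  The output is
    sorted and merged (zero gaps fuse neighbours).
    """
    if not rs.merged:
        raise ValueError(f"set {rs.name!r} must be merged before shuffling")
    genome.validate_set(rs)

    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in rs:
        by_chrom.setdefault(r.chrom, []).append(r)

    out: list[GenomicRegion] = []
    for chrom in rs.chromosomes():
        regions = by_chrom[chrom]
        chrom_len = genome.chrom_lengths[chrom]
        lengths = np.array([r.length for r in regions], dtype=np.int64)
        bounds = np.empty(2 * len(regions), dtype=np.int64)
        bounds[0::2] = [r.start for r in regions]
        bounds[1::2] = [r.end for r in regions]
        gaps = np.diff(np.concatenate(([0], bounds, [chrom_len])))[0::2]
        if lengths.sum() + gaps.sum() != chrom_len:
            raise ValueError(
                f"{rs.name}/{chrom}: regions exceed chromosome bounds"
            )
        lengths = rng.permutation(lengths)
        gaps = rng.permutation(gaps)
        # interleave gap, region, gap, region, ..., gap
        pos = 0
        for g, l in zip(gaps[:-1], lengths):
            pos += int(g)
            out.append(GenomicRegion(chrom, pos, pos + int(l)))
            pos += int(l)
    return merge_regions(RegionSet.from_iterable(rs.name, out))


def _shuffle_all(
    sets: Sequence[RegionSet],
    genome: Genome,
    locked: frozenset[str],
    seed: int,
    shuffle_index: int,
) -> list[RegionSet]:
    drawn = []
    for j, rs in enumerate(sets):
        if rs.name in locked:
            drawn.append(rs)
        else:
            drawn.append(shuffle_regions(rs, genome, _substream(seed, shuffle_index, j)))
    return drawn


def run_monte_carlo(
    sets: Sequence[RegionSet],
    genome: Genome,
    query_index: int | None = None,
    config: ShuffleConfig = ShuffleConfig(),
    mode: CountingMode = "transitive",
    combinations: Sequence[Combination] | None = None,
) -> ShuffleSamples:
    """Shuffle all non-locked sets ``n_shuffles`` times and recount.

    Tracked combinations are the union of those observed in the true data
    and in any shuffle (filtered to those containing the query if
    ``query_index`` is given), unless an explicit list is supplied.
    Results are independent of ``batch_size`` and of processing order.
    """
    if len(sets) < 2:
        raise ValueError("need at least two region sets")
    names = [rs.name for rs in sets]
    if config.locked_set_names - set(names):
        raise ValueError(f"unknown locked sets: {sorted(config.locked_set_names - set(names))}")
    if set(names) <= config.locked_set_names:
        raise ValueError("all sets are locked: the null model has no randomness")
    for rs in sets:
        genome.validate_set(rs)

    k = len(sets)
    # keep each shuffle's intersection rows in compact form, then count once
    # the tracked-combination list is known (a combination first seen late
    # still needs its transitive counts in earlier shuffles)
    per_shuffle: list[IntersectionMatrix] = []
    observed_masks: set[int] = set()

    truth = sweep_intersections(sets, genome)
    observed_masks.update(int(m) for m in np.unique(truth.masks))

    for s in range(config.n_shuffles):
        drawn = _shuffle_all(sets, genome, config.locked_set_names, config.seed, s)
        X = sweep_intersections(drawn, genome)
        per_shuffle.append(X)
        observed_masks.update(int(m) for m in np.unique(X.masks))

    if combinations is None:
        masks = sorted(observed_masks)
        if query_index is not None:
            if not (0 <= query_index < k):
                raise ValueError(f"query_index {query_index} out of range")
            qbit = 1 << query_index
            masks = [m for m in masks if m & qbit]
        tracked = [Combination.from_mask(m, k) for m in masks]
    else:
        tracked = list(combinations)

    samples = ShuffleSamples(names, mode, config.n_shuffles)
    for comb in tracked:
        samples.S[comb] = np.zeros(config.n_shuffles, dtype=np.int64)
        samples.N[comb] = np.zeros(config.n_shuffles, dtype=np.int64)
    for s, X in enumerate(per_shuffle):
        cc = count_combinations(X, mode=mode, combinations=tracked)
        for comb in tracked:
            S_val, N_val = cc.get(comb)
            samples.S[comb][s] = S_val
            samples.N[comb][s] = N_val
    return samples
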