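"""Sweep-line multiple intersection and combination counting.

The central object is the intersection matrix ``X``: one row per maximal
genomic window on which at least two region sets are simultaneously open,
with a boolean open flag per set and the window length.  A *combination*
is a subset of the k set identities; its measures are

* ``S`` — total base pairs on which the combination is observed, and
* ``N`` — number of contiguous windows carrying it.

Counting can be *exact* (a window counts only toward the precise flag
pattern open there) or *transitive* (a window also counts toward every
parent combination, i.e. every strict subset of its flags, with contiguous
windows merged a posteriori before counting N).  Transitive is the default:
under it "A + B" really stands for "A + B possibly with others".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .genome_model import Genome, RegionSet

__all__ = [
    "Combination",
    "IntersectionRow",
    "IntersectionMatrix",
    "CombinationCounts",
    "sweep_intersections",
    "count_combinations",
    "relate_combinations",
]

CountingMode = Literal["exact", "transitive"]


@dataclass(frozen=True)
class Combination:
    """A subset of the k set identities, stored as a fixed-length flag tuple."""

    flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", tuple(bool(f) for f in self.flags))
        if self.order < 1:
            raise ValueError("a combination involves at least one set")

    @property
    def k(self) -> int:
        return len(self.flags)

    @property
    def order(self) -> int:
        return sum(self.flags)

    @property
    def mask(self) -> int:
        m = 0
        for i, f in enumerate(self.flags):
            if f:
                m |= 1 << i
        return m

    @classmethod
    def from_mask(cls, mask: int, k: int) -> "Combination":
        return cls(tuple(bool(mask >> i & 1) for i in range(k)))

    @classmethod
    def from_names(cls, names: Sequence[str], set_names: Sequence[str]) -> "Combination":
        missing = set(names) - set(set_names)
        if missing:
            raise ValueError(f"unknown set names: {sorted(missing)}")
        return cls(tuple(n in set(names) for n in set_names))

    def members(self, set_names: Sequence[str]) -> list[str]:
        if len(set_names) != self.k:
            raise ValueError("set_names length does not match k")
        return [n for n, f in zip(set_names, self.flags) if f]

    def label(self, set_names: Sequence[str], transitive: bool = False) -> str:
        """Canonical rendering, sets in input order, '+'-joined.

        A trailing '...' marks transitive counting, where the combination
        stands for itself plus any additional sets.
        """
        inner = " + ".join(self.members(set_names))
        return f"[{inner} + ...]" if transitive else f"[{inner}]"


def relate_combinations(
    a: Combination, b: Combination
) -> Literal["parent", "child", "equal", "unrelated"]:
    """Partial order on combinations: a is parent of b iff a's sets are a
    strict subset of b's (the child is the more specific combination)."""
    if a.k != b.k:
        raise ValueError(f"combinations over different k: {a.k} vs {b.k}")
    am, bm = a.mask, b.mask
    if am == bm:
        return "equal"
    if am & bm == am:
        return "parent"
    if am & bm == bm:
        return "child"
    return "unrelated"


@dataclass(frozen=True)
class IntersectionRow:
    chrom: str
    start: int
    end: int
    flags: tuple[bool, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


class IntersectionMatrix:
    """Maximal constant-flag overlap windows, sorted by (chrom, start).

    Stored column-wise as numpy arrays for speed: ``chrom_ids`` indexes into
    ``chroms``, and ``masks`` packs the per-set open flags as bits (set i ->
    bit i), so k is limited to 64 sets — far above practical use.
    """

    def __init__(
        self,
        set_names: Sequence[str],
        chroms: Sequence[str],
        chrom_ids: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        masks: np.ndarray,
    ):
        self.set_names = list(set_names)
        self.chroms = list(chroms)
        self.chrom_ids = np.asarray(chrom_ids, dtype=np.int64)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.masks = np.asarray(masks, dtype=np.uint64)

    @property
    def k(self) -> int:
        return len(self.set_names)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[IntersectionRow]:
        for i in range(len(self)):
            yield IntersectionRow(
                self.chroms[self.chrom_ids[i]],
                int(self.starts[i]),
                int(self.ends[i]),
                tuple(bool(int(self.masks[i]) >> j & 1) for j in range(self.k)),
            )

    def flag_array(self) -> np.ndarray:
        """Rows as an (n, k) 0/1 integer array — the binary overlap matrix."""
        bits = (self.masks[:, None] >> np.arange(self.k, dtype=np.uint64)) & np.uint64(1)
        return bits.astype(np.int8)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [self.chroms[i] for i in self.chrom_ids],
                "start": self.starts,
                "end": self.ends,
            }
        )
        flags = self.flag_array()
        for j, name in enumerate(self.set_names):
            df[name] = flags[:, j]
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _set_events(rs: RegionSet, bit: int) -> tuple[dict[str, list[int]], dict[str, list[int]]]:
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for r in rs:
        starts.setdefault(r.chrom, []).append(r.start)
        ends.setdefault(r.chrom, []).append(r.end)
    return starts, ends


def sweep_intersections(sets: Sequence[RegionSet], genome: Genome | None = None) -> IntersectionMatrix:
    """Compute the intersection matrix of k >= 2 merged region sets.

    One pass per chromosome over the sorted critical points (region starts
    and ends); between consecutive critical points the per-set open flags
    are constant, and windows with >= 2 open sets become rows.  Events at
    the same coordinate are aggregated before emitting the next window, so
    abutting half-open intervals from different sets do not overlap.
    O(N log N) for the sort, then linear.
    """
    if len(sets) < 2:
        raise ValueError("need at least two region sets")
    if len(sets) > 64:
        raise ValueError("at most 64 sets supported")
    for rs in sets:
        if not rs.merged:
            raise ValueError(
                f"set {rs.name!r} is not merged; merge before sweeping so that "
                "per-set occupancy is boolean"
            )
        if genome is not None:
            genome.validate_set(rs)

    # bucket events per chromosome: +bit at start, -bit at end
    per_chrom: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for j, rs in enumerate(sets):
        bit = np.int64(1 << j)
        starts, ends = _set_events(rs, j)
        for chrom in starts:
            pos = np.concatenate(
                [np.asarray(starts[chrom], dtype=np.int64), np.asarray(ends[chrom], dtype=np.int64)]
            )
            delta = np.concatenate(
                [np.full(len(starts[chrom]), bit), np.full(len(ends[chrom]), -bit)]
            )
            per_chrom.setdefault(chrom, []).append((pos, delta))

    chroms = sorted(per_chrom)
    out_chrom_ids: list[np.ndarray] = []
    out_starts: list[np.ndarray] = []
    out_ends: list[np.ndarray] = []
    out_masks: list[np.ndarray] = []
    for cid, chrom in enumerate(chroms):
        pos = np.concatenate([p for p, _ in per_chrom[chrom]])
        delta = np.concatenate([d for _, d in per_chrom[chrom]])
        order = np.argsort(pos, kind="stable")
        pos, delta = pos[order], delta[order]
        # aggregate deltas at identical coordinates (close and open together)
        upos, idx = np.unique(pos, return_index=True)
        agg = np.add.reduceat(delta, idx)
        mask = np.cumsum(agg).astype(np.uint64)  # open-flag bitmask per segment
        seg_starts, seg_ends, seg_masks = upos[:-1], upos[1:], mask[:-1]
        # popcount >= 2 (numpy 2.x provides bitwise_count)
        keep = np.bitwise_count(seg_masks) >= 2
        if keep.any():
            out_chrom_ids.append(np.full(int(keep.sum()), cid, dtype=np.int64))
            out_starts.append(seg_starts[keep])
            out_ends.append(seg_ends[keep])
            out_masks.append(seg_masks[keep])

    if out_starts:
        return IntersectionMatrix(
            [rs.name for rs in sets],
            chroms,
            np.concatenate(out_chrom_ids),
            np.concatenate(out_starts),
            np.concatenate(out_ends),
            np.concatenate(out_masks),
        )
    return IntersectionMatrix(
        [rs.name for rs in sets],
        chroms,
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.uint64),
    )


@dataclass
class CombinationCounts:
    """Per-combination (S, N) pairs under one counting mode."""

    set_names: list[str]
    counts: dict[Combination, tuple[int, int]]
    mode: CountingMode

    def __getitem__(self, comb: Combination) -> tuple[int, int]:
        return self.counts[comb]

    def get(self, comb: Combination, default=(0, 0)) -> tuple[int, int]:
        return self.counts.get(comb, default)

    def combinations(self) -> list[Combination]:
        return list(self.counts)


def _transitive_counts_for_masks(
    X: IntersectionMatrix, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised transitive (S, N) for each target mask.

    A row counts toward target f iff its flags are a superset of f; for N,
    selected rows that are genomically contiguous are merged first.
    """
    S = np.zeros(len(targets), dtype=np.int64)
    N = np.zeros(len(targets), dtype=np.int64)
    if len(X) == 0:
        return S, N
    lengths = X.lengths
    # adjacency of consecutive rows (same chrom, end == next start)
    adj = np.zeros(len(X), dtype=bool)
    if len(X) > 1:
        adj[1:] = (X.chrom_ids[1:] == X.chrom_ids[:-1]) & (X.starts[1:] == X.ends[:-1])
    for i, f in enumerate(targets):
        sel = (X.masks & f) == f
        if not sel.any():
            continue
        S[i] = int(lengths[sel].sum())
        # windows: count selected rows not directly continuing a selected predecessor
        prev_sel = np.zeros(len(X), dtype=bool)
        prev_sel[1:] = sel[:-1]
        N[i] = int((sel & ~(adj & prev_sel)).sum())
    return S, N


def count_combinations(
    X: IntersectionMatrix,
    mode: CountingMode = "transitive",
    query_index: int | None = None,
    combinations: Sequence[Combination] | None = None,
) -> CombinationCounts:
    """Tally S and N per combination from an intersection matrix.

    By default every flag pattern observed in ``X`` is reported (restricted
    to those containing the query set when ``query_index`` is given).  An
    explicit ``combinations`` sequence overrides the observed list — useful
    for counting a fixed selection across shuffles.
    """
    if query_index is not None and not (0 <= query_index < X.k):
        raise ValueError(f"query_index {query_index} out of range for k={X.k}")

    uniq, inv = np.unique(X.masks, return_inverse=True) if len(X) else (
        np.empty(0, dtype=np.uint64),
        np.empty(0, dtype=np.int64),
    )

    if combinations is not None:
        for c in combinations:
            if c.k != X.k:
                raise ValueError("combination over wrong number of sets")
        targets = np.array([np.uint64(c.mask) for c in combinations], dtype=np.uint64)
    else:
        targets = uniq
        if query_index is not None:
            qbit = np.uint64(1 << query_index)
            targets = targets[(targets & qbit) != 0]

    counts: dict[Combination, tuple[int, int]] = {}
    if mode == "exact":
        # rows are maximal constant-flag windows, so exact N is the row count
        S_by_u = np.zeros(len(uniq), dtype=np.int64)
        N_by_u = np.zeros(len(uniq), dtype=np.int64)
        if len(X):
            np.add.at(S_by_u, inv, X.lengths)
            np.add.at(N_by_u, inv, 1)
        lut = {int(u): (int(s), int(n)) for u, s, n in zip(uniq, S_by_u, N_by_u)}
        for f in targets:
            counts[Combination.from_mask(int(f), X.k)] = lut.get(int(f), (0, 0))
    elif mode == "transitive":
        S, N = _transitive_counts_for_masks(X, targets)
        for f, s, n in zip(targets, S, N):
            counts[Combination.from_mask(int(f), X.k)] = (int(s), int(n))
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    return CombinationCounts([*X.set_names], counts, mode)
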