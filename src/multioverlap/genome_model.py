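"""Genomes, BED region sets, and sub-genome restriction.

Regions are plain position intervals in BED convention: 0-based, half-open
``[start, end)``, so a region covers ``end - start`` base pairs.  Strand and
any BED column beyond the third are ignored throughout; the overlap model
treats region sets purely as collections of intervals.

A *sub-genome restriction* concatenates user-selected regions of interest
(e.g. promoters, or the merged binding sites of all studied factors) into
shorter pseudo-chromosomes.  Both shuffling and counting then happen inside
that restricted space, which keeps long combinations observable under the
null when the regions of interest cover only a small fraction of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicRegion",
    "RegionSet",
    "Genome",
    "SubGenomeMap",
    "BedParseError",
    "read_regions",
    "read_chrom_sizes",
    "write_regions",
    "merge_regions",
    "subgenome_restrict",
]


class BedParseError(ValueError):
    """Raised when a BED or chromosome-sizes file cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionSet:
    """A named collection of regions, sorted by (chrom, start).

    ``merged`` records whether overlapping/abutting regions within the set
    have been fused; most downstream operations require merged input so that
    per-set occupancy at any base pair is a simple boolean.
    """

    name: str
    regions: tuple[GenomicRegion, ...]
    merged: bool = False

    def __post_init__(self) -> None:
        regs = tuple(self.regions)
        object.__setattr__(self, "regions", regs)
        for prev, cur in zip(regs, regs[1:]):
            if (cur.chrom, cur.start, cur.end) < (prev.chrom, prev.start, prev.end):
                raise ValueError(f"regions of {self.name!r} are not sorted")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    @property
    def total_bp(self) -> int:
        return sum(r.length for r in self.regions)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.chrom, None)
        return list(seen)

    @classmethod
    def from_iterable(cls, name: str, regions: Iterable[GenomicRegion]) -> "RegionSet":
        return cls(name, tuple(sorted(regions, key=lambda r: (r.chrom, r.start, r.end))))


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> length in bp."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def validate_set(self, rs: RegionSet) -> None:
        """Raise if any region falls outside the genome (no silent clipping)."""
        for r in rs:
            if r.chrom not in self.chrom_lengths:
                raise ValueError(f"{rs.name}: unknown chromosome {r.chrom!r}")
            if r.end > self.chrom_lengths[r.chrom]:
                raise ValueError(
                    f"{rs.name}: region {r.chrom}:{r.start}-{r.end} exceeds "
                    f"chromosome length {self.chrom_lengths[r.chrom]}"
                )


@dataclass(frozen=True)
class SubGenomeBlock:
    src_chrom: str
    src_start: int
    src_end: int
    target_chrom: str
    target_offset: int

    @property
    def length(self) -> int:
        return self.src_end - self.src_start


@dataclass(frozen=True)
class SubGenomeMap:
    """Invertible remapping of inclusion blocks onto concatenated pseudo-chromosomes.

    One pseudo-chromosome per source chromosome, so overlaps can never be
    manufactured across a chromosome boundary by the concatenation.
    """

    blocks: tuple[SubGenomeBlock, ...]

    def to_sub(self, region: GenomicRegion) -> list[GenomicRegion]:
        """Intersect with the blocks and remap; parts outside are discarded."""
        out = []
        for b in self.blocks:
            if b.src_chrom != region.chrom:
                continue
            lo = max(region.start, b.src_start)
            hi = min(region.end, b.src_end)
            if hi > lo:
                shift = b.target_offset - b.src_start
                out.append(GenomicRegion(b.target_chrom, lo + shift, hi + shift))
        return out

    def from_sub(self, region: GenomicRegion) -> list[GenomicRegion]:
        """Map a pseudo-chromosome interval back to source coordinates."""
        out = []
        for b in self.blocks:
            if b.target_chrom != region.chrom:
                continue
            lo = max(region.start, b.target_offset)
            hi = min(region.end, b.target_offset + b.length)
            if hi > lo:
                shift = b.src_start - b.target_offset
                out.append(GenomicRegion(b.src_chrom, lo + shift, hi + shift))
        return out


def read_regions(path: str | Path, name: str | None = None, merge: bool = True) -> RegionSet:
    """Read the first three columns of a BED file into a :class:`RegionSet`.

    Input sets are merged at load time by default (overlapping or abutting
    regions fused), since the null model and the overlap flags both assume
    at most one open region per set at any position.  Pass ``merge=False``
    to keep the raw intervals.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            regions.append(GenomicRegion(chrom, start, end))
    rs = RegionSet.from_iterable(name, regions)
    return merge_regions(rs) if merge else rs


def write_regions(rs: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as 3-column tab-separated BED."""
    with open(path, "w") as fh:
        for r in rs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_chrom_sizes(path: str | Path) -> Genome:
    """Read a UCSC-style two-column chromosome sizes file."""
    path = Path(path)
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            chrom = fields[0]
            if chrom in lengths:
                raise BedParseError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            try:
                lengths[chrom] = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer length") from exc
            if lengths[chrom] <= 0:
                raise BedParseError(f"{path}:{lineno}: non-positive length")
    if not lengths:
        raise BedParseError(f"{path}: no chromosomes")
    return Genome(lengths)


def merge_regions(rs: RegionSet) -> RegionSet:
    """Fuse overlapping or abutting regions within one set.

    Abutting intervals ([100,200) + [200,300)) are fused too: they cover
    contiguous base pairs, and window counting merges contiguous stretches
    anyway.  Total covered bp is preserved.
    """
    merged: list[GenomicRegion] = []
    for r in rs:
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            last = merged[-1]
            if r.end > last.end:
                merged[-1] = GenomicRegion(last.chrom, last.start, r.end)
        else:
            merged.append(r)
    return RegionSet(rs.name, tuple(merged), merged=True)


def subgenome_restrict(
    sets: Sequence[RegionSet],
    incl: RegionSet,
    genome: Genome,
) -> tuple[list[RegionSet], SubGenomeMap, Genome]:
    """Restrict analysis to the regions of ``incl``.

    The inclusion regions are merged and concatenated into one
    pseudo-chromosome per source chromosome; every input region is
    intersected with them and remapped.  Parts falling outside ``incl``
    are discarded.  Returns the restricted sets (merged), the invertible
    map, and the sub-genome sizes.
    """
    incl = merge_regions(incl)
    if len(incl) == 0:
        raise ValueError("inclusion set is empty")
    genome.validate_set(incl)

    blocks: list[SubGenomeBlock] = []
    offsets: dict[str, int] = {}
    for r in incl:
        target = f"sub_{r.chrom}"
        off = offsets.get(target, 0)
        blocks.append(SubGenomeBlock(r.chrom, r.start, r.end, target, off))
        offsets[target] = off + r.length
    sub_map = SubGenomeMap(tuple(blocks))
    sub_genome = Genome(dict(offsets))

    restricted = []
    for rs in sets:
        remapped: list[GenomicRegion] = []
        for region in rs:
            remapped.extend(sub_map.to_sub(region))
        restricted.append(
            merge_regions(RegionSet.from_iterable(rs.name, remapped))
        )
    return restricted, sub_map, sub_genome
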