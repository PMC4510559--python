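"""Core domain types for CNV call-set benchmarking.

A CNV call is a half-open genomic interval on an autosome carrying a copy
number (CN) *class* -- the direction of the variation (loss / normal /
gain) -- and optionally a CN *genotype*, the integer copy count 0-6 that
HMM-style callers report and that collapses onto a class.  All coordinates
are 0-based half-open (BED convention); positions are integer base pairs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

AUTOSOMES: tuple[int, ...] = tuple(range(1, 23))


class CNClass(str, enum.Enum):
    """Copy-number class: the categorical direction of a CNV."""

    LOSS = "loss"
    NORMAL = "normal"
    GAIN = "gain"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: CN classes that constitute an actual copy-number *variant*.
VARIANT_CLASSES: tuple[CNClass, CNClass] = (CNClass.LOSS, CNClass.GAIN)


def collapse_genotype_to_class(cn_genotype: int) -> CNClass:
    """Collapse an integer CN genotype (copies in a diploid genome) to a class.

    0 and 1 copies are losses, 2 is the diploid baseline, 3-6 are gains.

    Raises
    ------
    ValueError
        If the genotype is outside the supported 0-6 range.
    """
    if not isinstance(cn_genotype, (int, np.integer)) or isinstance(cn_genotype, bool):
        raise ValueError(f"CN genotype must be an integer, got {cn_genotype!r}")
    if cn_genotype in (0, 1):
        return CNClass.LOSS
    if cn_genotype == 2:
        return CNClass.NORMAL
    if 3 <= cn_genotype <= 6:
        return CNClass.GAIN
    raise ValueError(f"CN genotype out of range 0-6: {cn_genotype}")


def parse_chrom(value: object) -> int | None:
    """Parse a chromosome label to an autosome number, or None if not autosomal.

    Accepts ``1``, ``"1"``, ``"chr1"`` (any case).  Sex chromosomes,
    mitochondria and unplaced contigs map to None.
    """
    if isinstance(value, (int, np.integer)):
        c = int(value)
        return c if c in AUTOSOMES else None
    s = str(value).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        c = int(s)
    except ValueError:
        return None
    return c if c in AUTOSOMES else None


@dataclass(frozen=True)
class GenomicSegment:
    """One CNV call: a half-open interval with a CN class and provenance.

    ``start`` is 0-based inclusive, ``end`` is exclusive; ``length``
    is therefore ``end - start`` base pairs.
    """

    chrom: int
    start: int
    end: int
    cn_class: CNClass
    cn_genotype: int | None = None
    n_markers: int | None = None
    sample_id: str = ""
    tool_id: str = ""

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValueError(f"chromosome must be an autosome 1-22, got {self.chrom}")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if not isinstance(self.cn_class, CNClass):
            object.__setattr__(self, "cn_class", CNClass(self.cn_class))
        if self.cn_genotype is not None:
            implied = collapse_genotype_to_class(self.cn_genotype)
            if implied is not self.cn_class:
                raise ValueError(
                    f"CN genotype {self.cn_genotype} implies class {implied.value}, "
                    f"but segment is annotated {self.cn_class.value}"
                )
        if self.n_markers is not None and self.n_markers < 1:
            raise ValueError("n_markers must be a positive integer")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[int, int, int, str]:
        return (self.chrom, self.start, self.end, self.cn_class.value)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open integer intervals: sorted, overlapping or
    book-ended intervals coalesced."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged]


class CallSet:
    """All CNV calls for one (sample, tool) pair.

    Segments are kept sorted by (chrom, start).  A lazy per-(chromosome,
    class) index of *merged* interval bounds backs fast coverage queries;
    merging for the index never alters the stored segments.
    """

    __slots__ = ("sample_id", "tool_id", "segments", "_index")

    def __init__(
        self, sample_id: str, tool_id: str, segments: Iterable[GenomicSegment]
    ) -> None:
        self.sample_id = sample_id
        self.tool_id = tool_id
        stamped = (
            replace(s, sample_id=sample_id, tool_id=tool_id)
            if (s.sample_id, s.tool_id) != (sample_id, tool_id)
            else s
            for s in segments
        )
        self.segments: tuple[GenomicSegment, ...] = tuple(
            sorted(stamped, key=GenomicSegment.sort_key)
        )
        self._index: dict[tuple[int, CNClass], tuple[np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[GenomicSegment]:
        return iter(self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallSet):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.tool_id == other.tool_id
            and self.segments == other.segments
        )

    def __repr__(self) -> str:
        return (
            f"CallSet(sample_id={self.sample_id!r}, tool_id={self.tool_id!r}, "
            f"n_segments={len(self.segments)})"
        )

    def with_segments(self, segments: Iterable[GenomicSegment]) -> "CallSet":
        return CallSet(self.sample_id, self.tool_id, segments)

    def by_class(self, cn_class: CNClass) -> tuple[GenomicSegment, ...]:
        return tuple(s for s in self.segments if s.cn_class is cn_class)

    def merged_index(
        self, chrom: int, cn_class: CNClass
    ) -> tuple[np.ndarray, np.ndarray]:
        """Merged (starts, ends) arrays of this call set's segments on one
        chromosome and class.  Cached; arrays are disjoint and sorted."""
        key = (chrom, cn_class)
        cached = self._index.get(key)
        if cached is None:
            merged = merge_intervals(
                (s.start, s.end)
                for s in self.segments
                if s.chrom == chrom and s.cn_class is cn_class
            )
            starts = np.fromiter((s for s, _ in merged), dtype=np.int64, count=len(merged))
            ends = np.fromiter((e for _, e in merged), dtype=np.int64, count=len(merged))
            cached = (starts, ends)
            self._index[key] = cached
        return cached

    def total_length(self, cn_class: CNClass | None = None) -> int:
        """Total covered base pairs (per-base union within each class)."""
        classes = [cn_class] if cn_class is not None else list(VARIANT_CLASSES)
        total = 0
        for cls in classes:
            for chrom in sorted({s.chrom for s in self.segments if s.cn_class is cls}):
                starts, ends = self.merged_index(chrom, cls)
                total += int((ends - starts).sum())
        return total


@dataclass(frozen=True)
class Trio:
    offspring_id: str
    father_id: str
    mother_id: str
    population: str = ""

    def __post_init__(self) -> None:
        ids = {self.offspring_id, self.father_id, self.mother_id}
        if len(ids) != 3:
            raise ValueError(f"trio members must be distinct: {self}")


class Pedigree:
    """A collection of parent-offspring trios with population labels."""

    __slots__ = ("trios",)

    def __init__(self, trios: Iterable[Trio]) -> None:
        self.trios: tuple[Trio, ...] = tuple(trios)
        offspring = [t.offspring_id for t in self.trios]
        if len(offspring) != len(set(offspring)):
            raise ValueError("an individual appears more than once as offspring")

    def __len__(self) -> int:
        return len(self.trios)

    def __iter__(self) -> Iterator[Trio]:
        return iter(self.trios)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self.trios == other.trios

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.trios:
            seen.setdefault(t.population)
        return tuple(seen)

    def by_population(self, label: str) -> "Pedigree":
        return Pedigree(t for t in self.trios if t.population == label)

    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for t in self.trios:
            out.extend((t.offspring_id, t.father_id, t.mother_id))
        return out


class MarkerMap:
    """Array-marker positions on the genome.

    Maps marker ids to (chromosome, position) and supports fast counting of
    markers within an interval via per-chromosome sorted position arrays.
    """

    def __init__(self, entries: Iterable[tuple[str, int, int]]) -> None:
        self._pos: dict[str, tuple[int, int]] = {}
        per_chrom: dict[int, list[tuple[int, str]]] = {}
        for marker_id, chrom, position in entries:
            if marker_id in self._pos:
                raise ValueError(f"duplicate marker id {marker_id!r}")
            if chrom not in AUTOSOMES:
                raise ValueError(f"marker {marker_id!r} on non-autosome {chrom!r}")
            self._pos[marker_id] = (int(chrom), int(position))
            per_chrom.setdefault(int(chrom), []).append((int(position), marker_id))
        self._by_chrom: dict[int, tuple[np.ndarray, list[str]]] = {}
        for chrom, items in per_chrom.items():
            items.sort()
            positions = np.array([p for p, _ in items], dtype=np.int64)
            ids = [m for _, m in items]
            self._by_chrom[chrom] = (positions, ids)

    def __len__(self) -> int:
        return len(self._pos)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._pos

    def location(self, marker_id: str) -> tuple[int, int]:
        try:
            return self._pos[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def positions(self, chrom: int) -> np.ndarray:
        entry = self._by_chrom.get(chrom)
        return entry[0] if entry is not None else np.empty(0, dtype=np.int64)

    def marker_ids(self, chrom: int) -> list[str]:
        entry = self._by_chrom.get(chrom)
        return list(entry[1]) if entry is not None else []

    def count_in(self, chrom: int, start: int, end: int) -> int:
        """Number of markers with position in [start, end)."""
        pos = self.positions(chrom)
        return int(np.searchsorted(pos, end, side="left") - np.searchsorted(pos, start, side="left"))

    def iter_entries(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._by_chrom):
            positions, ids = self._by_chrom[chrom]
            for position, marker_id in zip(positions, ids):
                yield marker_id, chrom, int(position)


CallSetKey = tuple[str, str]  # (sample_id, tool_id)


def index_callsets(callsets: Iterable[CallSet]) -> dict[CallSetKey, CallSet]:
    """Key call sets by (sample_id, tool_id); duplicate keys are an error."""
    out: dict[CallSetKey, CallSet] = {}
    for cs in callsets:
        key = (cs.sample_id, cs.tool_id)
        if key in out:
            raise ValueError(f"duplicate call set for {key}")
        out[key] = cs
    return out


def tools_in(calls: Mapping[CallSetKey, CallSet]) -> list[str]:
    seen: dict[str, None] = {}
    for _, tool in calls:
        seen.setdefault(tool)
    return sorted(seen)
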