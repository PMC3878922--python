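"""Genome definitions, ground-truth events and interval sets.

Coordinates are 0-based half-open everywhere inside the package.  Report
writers convert to 1-based inclusive starts; interval lengths are always
``end - start`` on the internal half-open scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence


@dataclass(frozen=True)
class GenomeDef:
    """An ordered set of chromosomes with per-chromosome baseline ploidy.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs; names must be unique and
        lengths positive.
    ploidy_baseline
        Mapping chromosome name -> baseline integer copy number.  Defaults
        to 2 everywhere; set 1 for a male X/Y.
    """

    chromosomes: tuple[tuple[str, int], ...]
    ploidy_baseline: dict[str, int] = field(default_factory=dict)

    def __init__(
        self,
        chromosomes: Iterable[tuple[str, int]],
        ploidy_baseline: dict[str, int] | None = None,
    ):
        chroms = tuple((str(n), int(L)) for n, L in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for n, L in chroms:
            if L <= 0:
                raise ValueError(f"chromosome {n} has non-positive length {L}")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "ploidy_baseline", dict(ploidy_baseline or {}))
        for n in self.ploidy_baseline:
            if n not in names:
                raise ValueError(f"ploidy set for unknown chromosome {n!r}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for n, L in self.chromosomes:
            if n == chrom:
                return L
        raise KeyError(f"unknown chromosome {chrom!r}")

    def baseline(self, chrom: str) -> int:
        if chrom not in self.names:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.ploidy_baseline.get(chrom, 2)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names


EVENT_KINDS = ("gain", "loss", "cn_loh")


@dataclass(frozen=True)
class TruthEvent:
    """A ground-truth copy-number or copy-neutral LOH event.

    ``copy_number`` is the total copy number inside the event; for
    ``cn_loh`` it must equal the chromosome baseline (copy neutral).
    """

    chromosome: str
    start: int
    end: int
    kind: str
    copy_number: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"event start {self.start} >= end {self.end}")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1 (nullisomy not modeled)")

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate_against(self, genome: GenomeDef) -> None:
        L = genome.length(self.chromosome)
        if self.start < 0 or self.end > L:
            raise ValueError(
                f"event {self.chromosome}:{self.start}-{self.end} outside "
                f"chromosome bounds [0, {L})"
            )
        base = genome.baseline(self.chromosome)
        if self.kind == "gain" and not self.copy_number > base:
            raise ValueError(f"gain copy_number {self.copy_number} <= baseline {base}")
        if self.kind == "loss" and not self.copy_number < base:
            raise ValueError(f"loss copy_number {self.copy_number} >= baseline {base}")
        if self.kind == "cn_loh" and self.copy_number != base:
            raise ValueError(
                f"cn_loh copy_number {self.copy_number} != baseline {base}"
            )


def validate_events(genome: GenomeDef, events: Sequence[TruthEvent]) -> None:
    """Validate events against the genome and reject conflicting overlaps.

    Two events may not overlap unless they are the same kind and copy number
    (a duplicate); differing overlapping events are ambiguous.
    """
    for ev in events:
        ev.validate_against(genome)
    by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chromosome, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end and (a.kind, a.copy_number) != (b.kind, b.copy_number):
                raise ValueError(
                    f"conflicting overlapping events on {chrom}: "
                    f"{a.kind}@{a.start}-{a.end} vs {b.kind}@{b.start}-{b.end}"
                )


@dataclass(frozen=True)
class Interval:
    chromosome: str
    start: int
    end: int
    name: str = ""
    cls: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"interval start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A named list of genomic intervals tied to a :class:`GenomeDef`."""

    def __init__(
        self,
        intervals: Iterable[Interval | tuple],
        genome: GenomeDef,
        name: str = "",
    ):
        ivs = []
        for iv in intervals:
            if not isinstance(iv, Interval):
                iv = Interval(*iv)
            if iv.chromosome not in genome:
                raise ValueError(f"interval on unknown chromosome {iv.chromosome!r}")
            L = genome.length(iv.chromosome)
            if iv.start < 0 or iv.end > L:
                raise ValueError(
                    f"interval {iv.chromosome}:{iv.start}-{iv.end} outside [0, {L})"
                )
            ivs.append(iv)
        ivs.sort(key=lambda iv: (genome.names.index(iv.chromosome), iv.start, iv.end))
        self.intervals: list[Interval] = ivs
        self.genome = genome
        self.name = name

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def by_chromosome(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chromosome, []).append(iv)
        return out

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def same_genome(self, other: "IntervalSet") -> bool:
        return self.genome.chromosomes == other.genome.chromosomes


def child_seed(seed: int, offset: int) -> int:
    """Derive a per-stage child seed from a global seed by fixed offset.

    Kept below 2**31 so downstream RNGs accept it on any platform.
    """
    return (int(seed) * 1009 + int(offset)) % (2**31 - 1)
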