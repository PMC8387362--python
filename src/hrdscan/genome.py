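"""Genome layout and allele-specific copy-number segments.

Genomic scar scores (HRD-LOH, LST, TAI) need chromosome lengths and
centromere positions but no sequence, so the layout is a plain list of
chromosomes. The default layout is the hg19 autosome set.

Coordinates are 1-based inclusive throughout this module (SEG convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ChromosomeLayout",
    "GenomeLayout",
    "AlleleSpecificSegment",
    "hg19_autosomes",
    "sort_segments",
    "merge_equal_neighbors",
    "segment_at",
    "UncoveredLocusError",
    "OverlappingSegmentsError",
]


class UncoveredLocusError(ValueError):
    """A queried position is not covered by any segment."""


class OverlappingSegmentsError(ValueError):
    """A queried position is covered by more than one segment."""


@dataclass(frozen=True)
class ChromosomeLayout:
    name: str
    length: int
    centromere: int  # approximate centromere midpoint, bp

    def __post_init__(self) -> None:
        if not (0 < self.centromere < self.length):
            raise ValueError(
                f"centromere of {self.name} must lie inside the chromosome"
            )


@dataclass(frozen=True)
class GenomeLayout:
    """An ordered collection of chromosomes with centromere positions."""

    chromosomes: tuple[ChromosomeLayout, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def chromosome(self, name: str) -> ChromosomeLayout:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"chromosome {name!r} not in layout")

    def length(self, name: str) -> int:
        return self.chromosome(name).length

    def centromere(self, name: str) -> int:
        return self.chromosome(name).centromere

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


# UCSC hg19 autosome lengths; centromere midpoints rounded from the hg19
# cytoband p/q boundary.
_HG19_AUTOSOMES: tuple[tuple[str, int, int], ...] = (
    ("chr1", 249250621, 125000000),
    ("chr2", 243199373, 93300000),
    ("chr3", 198022430, 91000000),
    ("chr4", 191154276, 50400000),
    ("chr5", 180915260, 48400000),
    ("chr6", 171115067, 61000000),
    ("chr7", 159138663, 59900000),
    ("chr8", 146364022, 45600000),
    ("chr9", 141213431, 49000000),
    ("chr10", 135534747, 40200000),
    ("chr11", 135006516, 53700000),
    ("chr12", 133851895, 35800000),
    ("chr13", 115169878, 17900000),
    ("chr14", 107349540, 17600000),
    ("chr15", 102531392, 19000000),
    ("chr16", 90354753, 36600000),
    ("chr17", 81195210, 24000000),
    ("chr18", 78077248, 17200000),
    ("chr19", 59128983, 26500000),
    ("chr20", 63025520, 27500000),
    ("chr21", 48129895, 13200000),
    ("chr22", 51304566, 14700000),
)


def hg19_autosomes() -> GenomeLayout:
    """The default genome layout: the 22 hg19 autosomes."""
    return GenomeLayout(
        tuple(ChromosomeLayout(n, l, c) for n, l, c in _HG19_AUTOSOMES)
    )


@dataclass(frozen=True)
class AlleleSpecificSegment:
    """A genomic interval with total and minor integer copy number.

    ``minor_cn`` is the copy number of the less abundant allele, so
    ``minor_cn <= total_cn - minor_cn`` must hold. ``minor_cn == 0`` with
    ``total_cn >= 1`` is loss of heterozygosity; ``minor_cn != total_cn -
    minor_cn`` is allelic imbalance.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds major allele copy number "
                f"of a total of {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def major_cn(self) -> int:
        return self.total_cn - self.minor_cn

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.minor_cn)

    @property
    def is_loh(self) -> bool:
        return self.minor_cn == 0 and self.total_cn >= 1

    @property
    def is_allelic_imbalance(self) -> bool:
        return self.minor_cn != self.major_cn

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


def sort_segments(
    segments: Iterable[AlleleSpecificSegment],
) -> dict[str, list[AlleleSpecificSegment]]:
    """Group segments by chromosome, sorted by start coordinate."""
    by_chrom: dict[str, list[AlleleSpecificSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise OverlappingSegmentsError(
                    f"segments overlap on {chrom} at {b.start}"
                )
    return by_chrom


def merge_equal_neighbors(
    segs: Sequence[AlleleSpecificSegment],
) -> list[AlleleSpecificSegment]:
    """Merge contiguous segments carrying an identical copy state.

    Input must be sorted, non-overlapping segments of one chromosome.
    Segments are merged only when they abut exactly (no gap), so sparse
    profiles are left alone.
    """
    merged: list[AlleleSpecificSegment] = []
    for seg in segs:
        if (
            merged
            and merged[-1].state == seg.state
            and merged[-1].end + 1 == seg.start
        ):
            prev = merged.pop()
            seg = AlleleSpecificSegment(
                prev.chrom, prev.start, seg.end, prev.total_cn, prev.minor_cn
            )
        merged.append(seg)
    return merged


def segment_at(
    segments: Iterable[AlleleSpecificSegment], chrom: str, pos: int
) -> AlleleSpecificSegment:
    """Return the unique segment covering ``chrom:pos``.

    Raises :class:`UncoveredLocusError` when no segment covers the position
    and :class:`OverlappingSegmentsError` when more than one does. A position
    exactly on a boundary belongs to the segment whose interval contains it
    (1-based inclusive on both ends).
    """
    hits = [s for s in segments if s.contains(chrom, pos)]
    if not hits:
        raise UncoveredLocusError(f"{chrom}:{pos} not covered by any segment")
    if len(hits) > 1:
        raise OverlappingSegmentsError(
            f"{chrom}:{pos} covered by {len(hits)} segments"
        )
    return hits[0]
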