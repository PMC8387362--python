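"""Genomic scar scores for HRD detection: HRD-LOH, LST and TAI.

The three scores follow the canonical published criteria used by the
ScarHRD-family tools:

* HRD-LOH — number of LOH segments (minor copy number 0) longer than 15 Mb
  but shorter than the whole chromosome.
* LST (large-scale state transitions) — after smoothing away segments
  shorter than 3 Mb, the number of breakpoints between adjacent segments
  that are each at least 10 Mb long and differ in allele-specific copy
  state.
* TAI (telomeric allelic imbalance) — number of allelic-imbalance regions
  that extend to a telomere without crossing the centromere.

A tumor is scar-positive when the sum of the three scores is >= 42.
All length cutoffs are exposed as keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome import (
    AlleleSpecificSegment,
    GenomeLayout,
    merge_equal_neighbors,
    sort_segments,
)

__all__ = [
    "ScarScores",
    "score_hrd_loh",
    "score_lst",
    "score_tai",
    "scar_scores",
    "call_scar_hrd",
    "SCAR_HRD_THRESHOLD",
    "HRD_LOH_MIN_LENGTH",
    "LST_MIN_SEGMENT",
    "LST_SMOOTHING_LENGTH",
]

SCAR_HRD_THRESHOLD = 42
HRD_LOH_MIN_LENGTH = 15_000_000
LST_MIN_SEGMENT = 10_000_000
LST_SMOOTHING_LENGTH = 3_000_000


@dataclass(frozen=True)
class ScarScores:
    hrd_loh: int
    lst: int
    tai: int

    @property
    def total(self) -> int:
        return self.hrd_loh + self.lst + self.tai

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.hrd_loh, self.lst, self.tai)


def _prepared(segments: Iterable[AlleleSpecificSegment]):
    """Sorted, per-chromosome segments with equal neighbors merged."""
    by_chrom = sort_segments(segments)
    return {c: merge_equal_neighbors(s) for c, s in by_chrom.items()}


def score_hrd_loh(
    segments: Iterable[AlleleSpecificSegment],
    layout: GenomeLayout,
    min_length: int = HRD_LOH_MIN_LENGTH,
) -> int:
    """Count LOH segments longer than ``min_length`` that span less than a
    whole chromosome (whole-chromosome LOH carries no scar information)."""
    count = 0
    for chrom, segs in _prepared(segments).items():
        chrom_len = layout.length(chrom)
        for seg in segs:
            if not seg.is_loh:
                continue
            if seg.length <= min_length:
                continue
            if seg.length >= chrom_len:
                continue
            count += 1
    return count


def _smooth(
    segs: Sequence[AlleleSpecificSegment], min_length: int
) -> list[AlleleSpecificSegment]:
    """Remove segments shorter than ``min_length``.

    The shortest sub-threshold segment is removed first and its interval is
    absorbed by the longer flanking neighbor; neighbors that end up with an
    identical state are merged. Repeats until every segment is at least
    ``min_length`` (or a single segment remains).
    """
    segs = merge_equal_neighbors(segs)
    while len(segs) > 1:
        idx = min(range(len(segs)), key=lambda i: (segs[i].length, i))
        if segs[idx].length >= min_length:
            break
        victim = segs[idx]
        left = segs[idx - 1] if idx > 0 else None
        right = segs[idx + 1] if idx < len(segs) - 1 else None
        if left is not None and (right is None or left.length >= right.length):
            heir = AlleleSpecificSegment(
                left.chrom, left.start, victim.end, left.total_cn, left.minor_cn
            )
            segs = [*segs[: idx - 1], heir, *segs[idx + 1 :]]
        else:
            assert right is not None
            heir = AlleleSpecificSegment(
                right.chrom,
                victim.start,
                right.end,
                right.total_cn,
                right.minor_cn,
            )
            segs = [*segs[:idx], heir, *segs[idx + 2 :]]
        segs = merge_equal_neighbors(segs)
    return list(segs)


def score_lst(
    segments: Iterable[AlleleSpecificSegment],
    layout: GenomeLayout,
    min_segment: int = LST_MIN_SEGMENT,
    smoothing: int = LST_SMOOTHING_LENGTH,
) -> int:
    """Count large-scale state transitions.

    After smoothing away segments shorter than ``smoothing``, a breakpoint
    between two abutting segments counts when both are at least
    ``min_segment`` long and their (total, minor) states differ.
    """
    count = 0
    for chrom, segs in _prepared(segments).items():
        smoothed = _smooth(segs, smoothing)
        for a, b in zip(smoothed, smoothed[1:]):
            if b.start != a.end + 1:
                continue  # gap: not an observed transition
            if a.state == b.state:
                continue
            if a.length >= min_segment and b.length >= min_segment:
                count += 1
    return count


def score_tai(
    segments: Iterable[AlleleSpecificSegment],
    layout: GenomeLayout,
) -> int:
    """Count telomeric allelic-imbalance regions.

    Consecutive abutting segments in allelic imbalance are unioned into
    regions; a region counts when it reaches a telomere (position 1 or the
    chromosome end in the layout) and does not cross the centromere. A
    whole-chromosome AI region crosses the centromere and never counts.
    """
    count = 0
    for chrom, segs in _prepared(segments).items():
        chrom_len = layout.length(chrom)
        cen = layout.centromere(chrom)
        # union consecutive AI segments into maximal regions
        regions: list[tuple[int, int]] = []
        for seg in segs:
            if not seg.is_allelic_imbalance:
                continue
            if (
                regions
                and regions[-1][1] + 1 == seg.start
            ):
                regions[-1] = (regions[-1][0], seg.end)
            else:
                regions.append((seg.start, seg.end))
        for start, end in regions:
            touches_p = start == 1
            touches_q = end >= chrom_len
            if touches_p and end < cen:
                count += 1
            elif touches_q and start > cen:
                count += 1
    return count


def scar_scores(
    segments: Iterable[AlleleSpecificSegment],
    layout: GenomeLayout,
    hrd_loh_min_length: int = HRD_LOH_MIN_LENGTH,
    lst_min_segment: int = LST_MIN_SEGMENT,
    lst_smoothing: int = LST_SMOOTHING_LENGTH,
) -> ScarScores:
    segments = list(segments)
    return ScarScores(
        hrd_loh=score_hrd_loh(segments, layout, hrd_loh_min_length),
        lst=score_lst(segments, layout, lst_min_segment, lst_smoothing),
        tai=score_tai(segments, layout),
    )


def call_scar_hrd(
    hrd_loh: int, lst: int, tai: int, threshold: int = SCAR_HRD_THRESHOLD
) -> bool:
    """Scar-based HRD call: positive iff HRD-LOH + LST + TAI >= threshold."""
    if min(hrd_loh, lst, tai) < 0:
        raise ValueError("scar components must be non-negative")
    return hrd_loh + lst + tai >= threshold
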