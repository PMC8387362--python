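"""Somatic second-hit detection.

For each germline candidate variant the tumor's paired read counts are
tested for allelic imbalance with Pearson's chi-squared test (1 df, no
continuity correction by default) on the 2x2 table

    [[germline_ref, germline_alt],
     [tumor_ref,    tumor_alt   ]]

and the local allele-specific copy-number state converts a significant,
variant-retaining imbalance into an LOH type:

* DEL-LOH — total copy number 1 (WT allele deleted);
* CN-LOH  — total copy number 2 (variant allele duplicated, WT lost);
* DUP-LOH — total copy number >= 3 (variant allele multiplied, WT lost);

all requiring minor copy number 0 at the locus. Purely somatic two-hit
events (somatic loss-of-function plus LOH, no germline variant) are found
by :func:`somatic_biallelic_scan`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .genome import AlleleSpecificSegment, segment_at
from .variants import LOF_CONSEQUENCES, VariantObservation

__all__ = [
    "ZeroMarginError",
    "allelic_imbalance_test",
    "retention_direction",
    "classify_loh_type",
    "SecondHitResult",
    "evaluate_second_hit",
    "detect_somatic_second_hit",
    "somatic_biallelic_scan",
    "call_cn_events",
    "AI_P_CUTOFF",
    "AMPLIFICATION_GENES",
    "AMPLIFICATION_THRESHOLD",
]

AI_P_CUTOFF = 0.05
AMPLIFICATION_GENES = frozenset({"ERBB2", "MYC", "ZNF703"})
AMPLIFICATION_THRESHOLD = 6


class ZeroMarginError(ValueError):
    """The 2x2 table has a zero row or column margin; the test is undefined."""


def allelic_imbalance_test(
    g_ref,
    g_alt,
    t_ref,
    t_alt,
    continuity: bool = False,
):
    """Two-sided Pearson chi-squared p-value for germline-vs-tumor allele counts.

    Computed via the expected-counts route: E = outer(row, col) / N and
    X^2 = sum((O - E)^2 / E), referred to the chi-squared(1) survival
    function. ``continuity=True`` applies the Yates correction. Accepts
    scalars or equally shaped arrays (vectorized); scalar calls with a zero
    margin raise :class:`ZeroMarginError`.
    """
    scalar = np.isscalar(g_ref) or (np.ndim(g_ref) == 0)
    a = np.asarray(g_ref, dtype=float)
    b = np.asarray(g_alt, dtype=float)
    c = np.asarray(t_ref, dtype=float)
    d = np.asarray(t_alt, dtype=float)
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("read counts must be non-negative")
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    bad = (row1 == 0) | (row2 == 0) | (col1 == 0) | (col2 == 0)
    if scalar and bad:
        raise ZeroMarginError("zero margin: allelic-imbalance test undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.stack([a, b, c, d])
        exp = np.stack([row1 * col1, row1 * col2, row2 * col1, row2 * col2]) / n
        diff = np.abs(obs - exp)
        if continuity:
            diff = np.maximum(diff - 0.5, 0.0)
        stat = np.where(exp > 0, diff**2 / np.where(exp > 0, exp, 1.0), 0.0).sum(
            axis=0
        )
    p = chi2.sf(stat, df=1)
    p = np.where(bad, np.nan, p)
    return float(p) if scalar else p


def retention_direction(g_ref: int, g_alt: int, t_ref: int, t_alt: int) -> str:
    """'variant-retained' when the tumor VAF rises above the germline VAF,
    'wt-retained' when it falls, 'balanced' when equal."""
    g_depth, t_depth = g_ref + g_alt, t_ref + t_alt
    if g_depth <= 0 or t_depth <= 0:
        raise ZeroMarginError("retention direction undefined at zero depth")
    g_vaf = g_alt / g_depth
    t_vaf = t_alt / t_depth
    if t_vaf > g_vaf:
        return "variant-retained"
    if t_vaf < g_vaf:
        return "wt-retained"
    return "balanced"


def classify_loh_type(
    variant: VariantObservation,
    segments: Iterable[AlleleSpecificSegment],
    p_value: float,
    direction: str,
    alpha: float = AI_P_CUTOFF,
) -> str:
    """LOH retention type at the variant locus, or 'none'.

    A retention type is assigned only when the allelic-imbalance p-value is
    <= ``alpha`` (boundary inclusive), the tumor retains the variant allele,
    and the covering segment has minor copy number 0. A homozygous deletion
    (total 0) cannot retain the variant and maps to 'none'.
    """
    seg = segment_at(segments, variant.chrom, variant.pos)
    if p_value > alpha or direction != "variant-retained":
        return "none"
    if seg.minor_cn != 0:
        return "none"
    if seg.total_cn == 1:
        return "DEL-LOH"
    if seg.total_cn == 2:
        return "CN-LOH"
    if seg.total_cn >= 3:
        return "DUP-LOH"
    return "none"


@dataclass(frozen=True)
class SecondHitResult:
    """Allelic-imbalance and LOH evidence for one germline candidate."""

    variant_key: tuple[str, int, str, str]
    gene: str
    patient_id: str
    p_value: float
    direction: str
    retention: str  # DEL-LOH | DUP-LOH | CN-LOH | none
    somatic_point_hit: tuple[str, int, str, str] | None = None
    error: str = ""

    @property
    def has_second_hit(self) -> bool:
        return self.retention != "none" or self.somatic_point_hit is not None


def detect_somatic_second_hit(
    gene: str, somatic_variants: Sequence[VariantObservation]
) -> tuple[str, int, str, str] | None:
    """A filtered somatic loss-of-function or splice variant in ``gene``."""
    for v in somatic_variants:
        if v.gene_symbol == gene and v.consequence in LOF_CONSEQUENCES:
            return v.key
    return None


def evaluate_second_hit(
    variant: VariantObservation,
    segments: Iterable[AlleleSpecificSegment],
    somatic_variants: Sequence[VariantObservation] = (),
    alpha: float = AI_P_CUTOFF,
    continuity: bool = False,
) -> SecondHitResult:
    """Full second-hit evaluation for one germline candidate variant.

    Zero-margin tables and uncovered loci are treated as no evidence, with
    the reason recorded in ``error``.
    """
    segments = list(segments)
    point_hit = detect_somatic_second_hit(variant.gene_symbol, somatic_variants)
    try:
        p = allelic_imbalance_test(
            variant.germline_ref_count,
            variant.germline_alt_count,
            variant.tumor_ref_count,
            variant.tumor_alt_count,
            continuity=continuity,
        )
        direction = retention_direction(
            variant.germline_ref_count,
            variant.germline_alt_count,
            variant.tumor_ref_count,
            variant.tumor_alt_count,
        )
        retention = classify_loh_type(variant, segments, p, direction, alpha)
        error = ""
    except ZeroMarginError:
        p, direction, retention, error = float("nan"), "balanced", "none", "zero-margin"
    except ValueError as exc:
        p, direction, retention, error = float("nan"), "balanced", "none", str(exc)
    return SecondHitResult(
        variant_key=variant.key,
        gene=variant.gene_symbol,
        patient_id=variant.patient_id,
        p_value=p,
        direction=direction,
        retention=retention,
        somatic_point_hit=point_hit,
        error=error,
    )


def somatic_biallelic_scan(
    somatic_variants: Sequence[VariantObservation],
    segments: Iterable[AlleleSpecificSegment],
    candidate_genes: Iterable[str],
) -> list[tuple[str, tuple[str, int, str, str], str]]:
    """Purely somatic two-hit genes: somatic LoF/splice variant at an LOH locus.

    Returns ``(gene, variant key, retention type)`` tuples; retention type is
    derived from the covering segment's total copy number (1 DEL-LOH,
    2 CN-LOH, >= 3 DUP-LOH).
    """
    segments = list(segments)
    genes = set(candidate_genes)
    hits = []
    for v in somatic_variants:
        if v.consequence not in LOF_CONSEQUENCES or v.gene_symbol not in genes:
            continue
        try:
            seg = segment_at(segments, v.chrom, v.pos)
        except ValueError:
            continue
        if seg.minor_cn != 0 or seg.total_cn < 1:
            continue
        retention = {1: "DEL-LOH", 2: "CN-LOH"}.get(seg.total_cn, "DUP-LOH")
        hits.append((v.gene_symbol, v.key, retention))
    return hits


def call_cn_events(
    segments: Iterable[AlleleSpecificSegment],
    gene_intervals: Mapping[str, tuple[str, int, int]],
    amplification_genes: frozenset[str] = AMPLIFICATION_GENES,
    amplification_threshold: int = AMPLIFICATION_THRESHOLD,
) -> dict[str, str]:
    """Per-gene copy-number event calls.

    Total copy number 0 over the gene -> homozygous-deletion; 1 ->
    hemizygous-deletion; >= ``amplification_threshold`` for genes on the
    amplification panel -> amplification; otherwise none. Genes spanning
    several segments use the minimum total for losses and the maximum for
    amplification.
    """
    segments = list(segments)
    calls: dict[str, str] = {}
    for gene, (chrom, start, end) in gene_intervals.items():
        overlapping = [
            s for s in segments if s.chrom == chrom and s.start <= end and s.end >= start
        ]
        if not overlapping:
            calls[gene] = "none"
            continue
        totals = [s.total_cn for s in overlapping]
        if min(totals) == 0:
            calls[gene] = "homozygous-deletion"
        elif min(totals) == 1:
            calls[gene] = "hemizygous-deletion"
        elif max(totals) >= amplification_threshold and gene in amplification_genes:
            calls[gene] = "amplification"
        else:
            calls[gene] = "none"
    return calls
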