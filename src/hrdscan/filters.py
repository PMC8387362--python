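"""Germline candidate selection and somatic variant filtering.

Germline quality rules (applied in order; a removed variant is tagged with
the first failing rule):

  (i)   position covered by < 5 reads
  (ii)  < 2 reads support the alternate allele
  (iii) allelic fraction outside the heterozygote window [0.35, 0.65]
  (iv)  mapping quality < 30

The heterozygote window default is the standard symmetric QC band; all four
thresholds are configurable. Candidates then pass a population-frequency
screen (max AF across sources < 0.01, unobserved treated as 0 — novel
variants are the search target) and are routed by ClinVar/ACMG class,
consequence, gene category, and an in-silico predictor quorum (deleterious
by >= 4 of 8 tools; missense variants in clinical BCSG panel genes are kept
regardless of predictor scores).

Somatic filters (first failing rule tagged, FFPE-oriented):

  (i)   strand bias — exact two-sided binomial test of the alternate-read
        forward/reverse split against the reference-read strand ratio;
        removed when p < 0.01 with >= 6 alternate reads
  (ii)  germline in origin (present among matched germline calls)
  (iii) present in the panel of normals (PoN)
  (iv)  tumor depth < 10 reads
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import binomtest

from .genes import GeneLists, assign_gene_category
from .variants import (
    PREDICTOR_NAMES,
    TRUNCATING_CONSEQUENCES,
    VariantObservation,
)

__all__ = [
    "GermlineQualityThresholds",
    "SomaticFilterThresholds",
    "FilterOutcome",
    "filter_germline_quality",
    "filter_population_frequency",
    "predictor_consensus",
    "route_candidate",
    "filter_somatic",
    "BENIGN_CLASSES",
    "DISPOSITIONS",
]

BENIGN_CLASSES = frozenset({"Benign", "Likely benign"})
DISPOSITIONS = (
    "master-list",
    "dropped-benign",
    "dropped-prediction",
    "dropped-consequence",
)


@dataclass(frozen=True)
class GermlineQualityThresholds:
    min_depth: int = 5
    min_alt_reads: int = 2
    af_low: float = 0.35
    af_high: float = 0.65
    min_mapping_quality: float = 30.0


@dataclass(frozen=True)
class SomaticFilterThresholds:
    strand_bias_p: float = 0.01
    strand_bias_min_alt: int = 6
    min_depth: int = 10


@dataclass
class FilterOutcome:
    """Partition of input variants into kept and removed-with-reason."""

    kept: list[VariantObservation] = field(default_factory=list)
    removed: list[tuple[VariantObservation, str]] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.removed)

    def removal_reasons(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.removed:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


def filter_germline_quality(
    variants: Iterable[VariantObservation],
    thresholds: GermlineQualityThresholds | None = None,
) -> FilterOutcome:
    """Apply germline quality rules (i)-(iv); see module docstring.

    Both window endpoints are kept (inclusive). Variants with missing
    germline counts are removed with reason 'unscorable'.
    """
    t = thresholds or GermlineQualityThresholds()
    out = FilterOutcome()
    for v in variants:
        depth = v.germline_depth
        if depth is None:
            out.removed.append((v, "unscorable"))
            continue
        if depth < t.min_depth:
            out.removed.append((v, "i:low-depth"))
            continue
        if v.germline_alt_count < t.min_alt_reads:
            out.removed.append((v, "ii:low-alt-support"))
            continue
        af = v.germline_af
        if af is None or not (t.af_low <= af <= t.af_high):
            out.removed.append((v, "iii:allelic-fraction"))
            continue
        if v.mapping_quality is None or v.mapping_quality < t.min_mapping_quality:
            out.removed.append((v, "iv:low-mapping-quality"))
            continue
        out.kept.append(v)
    return out


def filter_population_frequency(
    variants: Iterable[VariantObservation], threshold: float = 0.01
) -> FilterOutcome:
    """Keep variants whose maximum population allele frequency is strictly
    below ``threshold``; an absent frequency counts as 0 (kept)."""
    out = FilterOutcome()
    for v in variants:
        af = v.population_af or 0.0
        if af < threshold:
            out.kept.append(v)
        else:
            out.removed.append((v, "population-frequency"))
    return out


def predictor_consensus(
    predictor_calls: Sequence[bool | None], quorum: int = 4
) -> bool:
    """True when >= ``quorum`` of the eight predictors call deleterious.

    Absent calls (None) count toward the denominator of eight, never the
    numerator. More than eight calls is an input error.
    """
    if len(predictor_calls) > len(PREDICTOR_NAMES):
        raise ValueError(
            f"at most {len(PREDICTOR_NAMES)} predictor calls allowed, "
            f"got {len(predictor_calls)}"
        )
    return sum(1 for c in predictor_calls if c is True) >= quorum


def _effective_class(variant: VariantObservation) -> str:
    """ClinVar class, falling back to ACMG when ClinVar is uninformative."""
    if variant.clinvar_class not in ("Unknown", "", None):
        return variant.clinvar_class
    return variant.acmg_class or "Unknown"


def route_candidate(
    variant: VariantObservation,
    category: str,
    predictor_quorum: int = 4,
) -> str:
    """Disposition of a quality- and frequency-passing germline variant.

    Benign/likely-benign (ClinVar, or ACMG when ClinVar is absent) ->
    'dropped-benign'. Truncating or splice -> 'master-list'. Missense in a
    BCSG -> 'master-list' regardless of predictors; missense elsewhere needs
    the predictor quorum, otherwise 'dropped-prediction'.
    Synonymous/other -> 'dropped-consequence'.
    """
    if _effective_class(variant) in BENIGN_CLASSES:
        return "dropped-benign"
    cons = variant.consequence
    if cons in TRUNCATING_CONSEQUENCES or cons == "splice":
        return "master-list"
    if cons == "missense":
        if category == "BCSG":
            return "master-list"
        if predictor_consensus(variant.predictor_calls, predictor_quorum):
            return "master-list"
        return "dropped-prediction"
    return "dropped-consequence"


def select_germline_candidates(
    variants: Iterable[VariantObservation],
    gene_lists: GeneLists,
    quality: GermlineQualityThresholds | None = None,
    af_threshold: float = 0.01,
    predictor_quorum: int = 4,
) -> tuple[list[tuple[VariantObservation, str]], list[tuple[VariantObservation, str]]]:
    """Full germline candidate selection: quality -> frequency -> routing.

    Returns ``(master_list, removed)`` where master_list pairs each candidate
    with its gene category and removed pairs each variant with its reason.
    Variants in genes on none of the four lists are not candidates.
    """
    removed: list[tuple[VariantObservation, str]] = []
    q = filter_germline_quality(variants, quality)
    removed.extend(q.removed)
    f = filter_population_frequency(q.kept, af_threshold)
    removed.extend(f.removed)
    master: list[tuple[VariantObservation, str]] = []
    for v in f.kept:
        category = assign_gene_category(v.gene_symbol, gene_lists)
        if category == "other":
            removed.append((v, "not-a-candidate-gene"))
            continue
        disposition = route_candidate(v, category, predictor_quorum)
        if disposition == "master-list":
            master.append((v, category))
        else:
            removed.append((v, disposition))
    return master, removed


def _strand_biased(
    v: VariantObservation, p_cutoff: float, min_alt: int
) -> bool:
    if v.strand_alt_counts is None:
        return False
    fwd, rev = v.strand_alt_counts
    n = fwd + rev
    if n < min_alt:
        return False
    if v.strand_ref_counts is not None and sum(v.strand_ref_counts) > 0:
        ref_fwd, ref_rev = v.strand_ref_counts
        expected = ref_fwd / (ref_fwd + ref_rev)
        expected = min(max(expected, 1e-6), 1 - 1e-6)
    else:
        expected = 0.5
    p = binomtest(fwd, n, expected, alternative="two-sided").pvalue
    return p < p_cutoff


def filter_somatic(
    variants: Iterable[VariantObservation],
    pon: set[tuple[str, int, str, str]],
    matched_germline: set[tuple[str, int, str, str]],
    thresholds: SomaticFilterThresholds | None = None,
) -> FilterOutcome:
    """Apply somatic filters (i)-(iv); see module docstring."""
    t = thresholds or SomaticFilterThresholds()
    out = FilterOutcome()
    for v in variants:
        if _strand_biased(v, t.strand_bias_p, t.strand_bias_min_alt):
            out.removed.append((v, "i:strand-bias"))
            continue
        if v.key in matched_germline:
            out.removed.append((v, "ii:germline-origin"))
            continue
        if v.key in pon:
            out.removed.append((v, "iii:panel-of-normals"))
            continue
        depth = v.tumor_depth
        if depth is None or depth < t.min_depth:
            out.removed.append((v, "iv:low-depth"))
            continue
        out.kept.append(v)
    return out
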