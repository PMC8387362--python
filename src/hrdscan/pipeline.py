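"""In-memory pipeline orchestration: filter -> second hit -> HRD -> nominate.

The file-based entry point (config, CLI) lives in :mod:`hrdscan.io` /
:mod:`hrdscan.cli`; this module wires the analysis stages for objects
already in memory, which is also how the test-suite and the synthetic
cohorts drive it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import PipelineConfig
from .filters import FilterOutcome, filter_somatic, select_germline_candidates
from .genes import GeneLists
from .genome import AlleleSpecificSegment, GenomeLayout, hg19_autosomes
from .nominate import (
    CandidateReport,
    CoMutationSummary,
    build_comutation_summary,
    nominate,
)
from .scars import call_scar_hrd, scar_scores
from .secondhit import (
    SecondHitResult,
    evaluate_second_hit,
    somatic_biallelic_scan,
)
from .signatures import (
    HRDCall,
    Sig3Calibration,
    SignatureMatrix,
    build_96_catalog,
    calibrate_sig3_threshold,
    call_sig3,
    consensus_hrd,
    synthetic_signature_matrix,
)
from .variants import VariantObservation

logger = logging.getLogger("hrdscan")

__all__ = ["PipelineResult", "compute_hrd_call", "analyze_cohort"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one cohort."""

    candidates: list[tuple[VariantObservation, str]]
    germline_removed: list[tuple[VariantObservation, str]]
    somatic_kept: dict[str, list[VariantObservation]]
    somatic_removed: dict[str, list[tuple[VariantObservation, str]]]
    hrd_calls: dict[str, HRDCall]
    second_hits: dict[tuple, SecondHitResult]
    biallelic_somatic: dict[str, list]
    reports: list[CandidateReport]
    comutation: CoMutationSummary
    calibration: Sig3Calibration

    def nominated(self) -> list[CandidateReport]:
        return [r for r in self.reports if r.verdict == "hrd-candidate-pathogenic"]


def compute_hrd_call(
    somatic_kept: Sequence[VariantObservation],
    segments: Sequence[AlleleSpecificSegment],
    matrix: SignatureMatrix,
    calibration: Sig3Calibration,
    layout: GenomeLayout,
    config: PipelineConfig,
) -> HRDCall:
    """Per-tumor HRD call: Signature-3 LLR test on the filtered somatic
    catalog, scar scores from the segment profile, and their consensus."""
    snvs = [
        {"ref": v.ref_allele, "alt": v.alt_allele, "context": v.context}
        for v in somatic_kept
        if v.context and len(v.ref_allele) == 1 and len(v.alt_allele) == 1
    ]
    catalog = build_96_catalog(snvs)
    sig3 = call_sig3(catalog, matrix, calibration)
    scars = scar_scores(
        segments,
        layout,
        hrd_loh_min_length=config.hrd_loh_min_length,
        lst_min_segment=config.lst_min_segment,
        lst_smoothing=config.lst_smoothing,
    )
    scar_positive = call_scar_hrd(
        scars.hrd_loh, scars.lst, scars.tai, threshold=config.scar_threshold
    )
    return HRDCall(
        sig3_present=sig3.present,
        sig3_exposure=sig3.exposure,
        sig3_score=sig3.score,
        hrd_loh=scars.hrd_loh,
        lst=scars.lst,
        tai=scars.tai,
        scar_positive=scar_positive,
        consensus_positive=consensus_hrd(sig3.present, scar_positive),
        flag=sig3.flag,
    )


def analyze_cohort(
    germline: Sequence[VariantObservation],
    somatic: Sequence[VariantObservation],
    segments: Mapping[str, Sequence[AlleleSpecificSegment]],
    pon: set,
    gene_lists: GeneLists,
    config: PipelineConfig | None = None,
    signature_matrix: SignatureMatrix | None = None,
    calibration: Sig3Calibration | None = None,
    layout: GenomeLayout | None = None,
) -> PipelineResult:
    """Run the full analysis on an in-memory cohort.

    Patients are defined by the keys of ``segments``. Germline candidate
    selection and somatic filtering run per patient; HRD calls combine the
    Signature-3 test (threshold calibrated once per run unless a calibration
    is supplied) with the scar score; second hits are evaluated for every
    master-list candidate; nomination integrates the three.
    """
    config = config or PipelineConfig()
    layout = layout or hg19_autosomes()
    matrix = signature_matrix or synthetic_signature_matrix()
    if calibration is None:
        logger.info("calibrating Signature-3 threshold (fpr=%g)", config.sig3_fpr)
        calibration = calibrate_sig3_threshold(
            matrix,
            n_sims=config.sig3_calibration_sims,
            fpr=config.sig3_fpr,
            seed=config.seed,
            min_mutations=config.sig3_min_mutations,
        )

    patients = sorted(segments)
    germline_by_patient: dict[str, list[VariantObservation]] = {p: [] for p in patients}
    for v in germline:
        germline_by_patient.setdefault(v.patient_id, []).append(v)
    somatic_by_patient: dict[str, list[VariantObservation]] = {p: [] for p in patients}
    for v in somatic:
        somatic_by_patient.setdefault(v.patient_id, []).append(v)

    # stage 1: germline candidate selection
    candidates: list[tuple[VariantObservation, str]] = []
    germline_removed: list[tuple[VariantObservation, str]] = []
    for pid in patients:
        master, removed = select_germline_candidates(
            germline_by_patient.get(pid, []),
            gene_lists,
            quality=config.germline_thresholds(),
            af_threshold=config.population_af_threshold,
            predictor_quorum=config.predictor_quorum,
        )
        candidates.extend(master)
        germline_removed.extend(removed)

    # stage 2: somatic filtering (matched germline = the patient's calls)
    somatic_kept: dict[str, list[VariantObservation]] = {}
    somatic_removed: dict[str, list[tuple[VariantObservation, str]]] = {}
    for pid in patients:
        matched = {v.key for v in germline_by_patient.get(pid, [])}
        outcome: FilterOutcome = filter_somatic(
            somatic_by_patient.get(pid, []),
            pon=pon,
            matched_germline=matched,
            thresholds=config.somatic_thresholds(),
        )
        somatic_kept[pid] = outcome.kept
        somatic_removed[pid] = outcome.removed

    # stage 3: HRD per tumor
    hrd_calls = {
        pid: compute_hrd_call(
            somatic_kept[pid], segments[pid], matrix, calibration, layout, config
        )
        for pid in patients
    }

    # stage 4: second hits for every candidate
    second_hits: dict[tuple, SecondHitResult] = {}
    for variant, _category in candidates:
        pid = variant.patient_id
        second_hits[(pid, variant.key)] = evaluate_second_hit(
            variant,
            segments[pid],
            somatic_kept.get(pid, []),
            alpha=config.ai_p_cutoff,
            continuity=config.continuity,
        )

    # purely somatic two-hit genes (reported alongside, never nominated)
    biallelic = {
        pid: somatic_biallelic_scan(
            somatic_kept[pid], segments[pid], gene_lists.all_genes
        )
        for pid in patients
    }

    # stage 5: nomination + co-mutation summary
    reports = nominate(
        candidates,
        second_hits,
        hrd_calls,
        caveat_genes=frozenset(config.caveat_genes),
        require_consensus=config.require_consensus,
    )
    comutation = build_comutation_summary(reports, hrd_calls)

    return PipelineResult(
        candidates=candidates,
        germline_removed=germline_removed,
        somatic_kept=somatic_kept,
        somatic_removed=somatic_removed,
        hrd_calls=hrd_calls,
        second_hits=second_hits,
        biallelic_somatic=biallelic,
        reports=reports,
        comutation=comutation,
        calibration=calibration,
    )
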