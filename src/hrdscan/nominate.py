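"""Final candidate nomination: germline candidate + second hit + HRD tumor.

A germline candidate variant is re-classified as behaving like a pathogenic
HRD susceptibility allele only when, in the same patient and gene, the
tumor shows a somatic second hit (LOH retention or a somatic
loss-of-function point event) *and* the tumor is HRD by the two-caller
consensus (Signature 3 present AND scar score >= 42). Candidates with a
second hit in a non-HRD tumor are 'second-hit-only'; consensus-HRD patients
without any candidate are 'hrd-no-candidate'; everything else is
'no-evidence'.

Biallelic CHEK2 loss is not Signature-3 associated, so genes on the caveat
list (default: CHEK2) are downgraded from 'hrd-candidate-pathogenic' to
'second-hit-only'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .secondhit import SecondHitResult
from .signatures import HRDCall
from .variants import VariantObservation

__all__ = [
    "VERDICTS",
    "DEFAULT_CAVEAT_GENES",
    "CandidateReport",
    "IncompletePatientError",
    "nominate",
    "lof_frequency",
    "driver_recurrence",
    "CoMutationSummary",
    "build_comutation_summary",
]

VERDICTS = (
    "hrd-candidate-pathogenic",
    "second-hit-only",
    "hrd-no-candidate",
    "no-evidence",
)

#: Genes whose biallelic loss is not Signature-3 associated; a second hit in
#: these genes cannot re-classify the germline variant.
DEFAULT_CAVEAT_GENES = frozenset({"CHEK2"})


class IncompletePatientError(ValueError):
    """A patient is present in one pipeline stage but missing from another."""


@dataclass(frozen=True)
class CandidateReport:
    """Per patient-gene integration of candidate, second hit and HRD status."""

    patient_id: str
    gene: str  # "" for patient-level hrd-no-candidate rows
    verdict: str
    category: str = ""
    variant_key: tuple | None = None
    clinvar_class: str = ""
    acmg_class: str | None = None
    consequence: str = ""
    retention: str = "none"
    p_value: float = float("nan")
    somatic_point_hit: tuple | None = None
    consensus_hrd: bool | None = None
    scar_sum: int | None = None
    sig3_present: bool | None = None
    caveat: str = ""
    lof_freq: float | None = None


def nominate(
    candidates: Sequence[tuple[VariantObservation, str]],
    second_hits: Mapping[tuple, SecondHitResult],
    hrd_calls: Mapping[str, HRDCall],
    caveat_genes: frozenset[str] = DEFAULT_CAVEAT_GENES,
    require_consensus: bool = True,
) -> list[CandidateReport]:
    """Assign one verdict per candidate (and per candidate-free HRD patient).

    ``candidates`` pairs each master-list germline variant with its gene
    category; ``second_hits`` maps (patient_id, variant key) to the
    second-hit evaluation; ``hrd_calls`` maps patient id to the tumor HRD
    call. ``require_consensus=False`` relaxes the HRD requirement to
    Signature-3 presence alone.
    """
    reports: list[CandidateReport] = []
    patients_with_candidates = set()
    for variant, category in candidates:
        pid = variant.patient_id
        patients_with_candidates.add(pid)
        if pid not in hrd_calls:
            raise IncompletePatientError(
                f"patient {pid} has candidates but no HRD call"
            )
        sh_key = (pid, variant.key)
        if sh_key not in second_hits:
            raise IncompletePatientError(
                f"patient {pid} candidate {variant.key} lacks a second-hit result"
            )
        sh = second_hits[sh_key]
        hrd = hrd_calls[pid]
        hrd_ok = (
            hrd.consensus_positive if require_consensus else hrd.sig3_present
        )
        caveat = ""
        if sh.has_second_hit and hrd_ok:
            verdict = "hrd-candidate-pathogenic"
            if variant.gene_symbol in caveat_genes:
                verdict = "second-hit-only"
                caveat = (
                    f"{variant.gene_symbol}: biallelic loss not "
                    "Signature-3-associated; not reclassifiable here"
                )
        elif sh.has_second_hit:
            verdict = "second-hit-only"
        else:
            verdict = "no-evidence"
        reports.append(
            CandidateReport(
                patient_id=pid,
                gene=variant.gene_symbol,
                verdict=verdict,
                category=category,
                variant_key=variant.key,
                clinvar_class=variant.clinvar_class,
                acmg_class=variant.acmg_class,
                consequence=variant.consequence,
                retention=sh.retention,
                p_value=sh.p_value,
                somatic_point_hit=sh.somatic_point_hit,
                consensus_hrd=hrd.consensus_positive,
                scar_sum=hrd.scar_sum,
                sig3_present=hrd.sig3_present,
                caveat=caveat,
            )
        )
    for pid, hrd in hrd_calls.items():
        if pid in patients_with_candidates:
            continue
        if hrd.consensus_positive:
            reports.append(
                CandidateReport(
                    patient_id=pid,
                    gene="",
                    verdict="hrd-no-candidate",
                    consensus_hrd=hrd.consensus_positive,
                    scar_sum=hrd.scar_sum,
                    sig3_present=hrd.sig3_present,
                )
            )
    # most damaging consequence first within each patient-gene group
    damage_rank = {
        "nonsense": 0, "frameshift": 1, "splice": 2, "missense": 3,
        "synonymous": 4, "other": 5, "": 6,
    }
    reports.sort(
        key=lambda r: (r.patient_id, r.gene, damage_rank.get(r.consequence, 9))
    )
    return reports


def lof_frequency(s: float, m: float) -> float:
    """Population loss-of-function allele frequency: 2 * S / m, with S the
    allelic count of LoF variants and m the median total allele number."""
    if m <= 0:
        raise ValueError("median allele number m must be positive")
    if s < 0:
        raise ValueError("allelic count S must be non-negative")
    return 2.0 * s / m


def driver_recurrence(
    somatic_variants: Iterable[VariantObservation],
    driver_genes: Iterable[str],
    q_scores: Mapping[str, float] | None = None,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Recurrently mutated driver genes across the cohort.

    Counts patients with at least one somatic variant per driver gene. With
    externally supplied q-scores, a gene is flagged as a driver when it is
    mutated more than once and its q-score is below ``q_cutoff``; without
    q-scores only counts are reported (flag column absent).
    """
    drivers = sorted(set(driver_genes))
    per_gene_patients: dict[str, set] = {g: set() for g in drivers}
    for v in somatic_variants:
        if v.gene_symbol in per_gene_patients:
            per_gene_patients[v.gene_symbol].add(v.patient_id)
    df = pd.DataFrame(
        {"gene": drivers, "n_mutated": [len(per_gene_patients[g]) for g in drivers]}
    )
    if q_scores is not None:
        df["q_score"] = [q_scores.get(g, float("nan")) for g in drivers]
        df["driver_flag"] = (df["n_mutated"] > 1) & (df["q_score"] < q_cutoff)
    return df


@dataclass
class CoMutationSummary:
    """Gene x patient event matrix with per-patient HRD header rows."""

    matrix: pd.DataFrame  # rows: genes (grouped by category); columns: patients
    hrd_rows: pd.DataFrame  # rows: sig3 / scar / consensus; columns: patients
    category_of: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Single serializable frame: HRD rows on top, then gene rows."""
        top = self.hrd_rows.copy()
        top.insert(0, "category", "HRD")
        genes = self.matrix.copy()
        genes.insert(
            0, "category", [self.category_of.get(g, "") for g in genes.index]
        )
        return pd.concat([top, genes])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="row")

    def plot(self, path) -> None:
        """Render a simple oncoprint-style tile plot to ``path``."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import numpy as np

        codes = {"": 0, "germline": 1, "somatic": 2, "CN-LOH": 3,
                 "DEL-LOH": 4, "DUP-LOH": 5, "point-hit": 6}
        frame = self.matrix
        data = np.array(
            [[codes.get(str(v), 7) for v in row] for row in frame.to_numpy()]
        )
        if data.size == 0:
            data = np.zeros((1, max(len(frame.columns), 1)))
        fig, ax = plt.subplots(
            figsize=(max(4, 0.4 * data.shape[1] + 2), max(3, 0.3 * data.shape[0] + 2))
        )
        ax.imshow(data, aspect="auto", cmap="tab10", vmin=0, vmax=9)
        ax.set_xticks(range(len(frame.columns)))
        ax.set_xticklabels(frame.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(frame.index)))
        ax.set_yticklabels(frame.index, fontsize=6)
        ax.set_title("Co-mutation summary")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_comutation_summary(
    reports: Sequence[CandidateReport],
    hrd_calls: Mapping[str, HRDCall],
    category_order: Sequence[str] = ("BCSG", "CSG", "DNA-repair", "C-HRG"),
) -> CoMutationSummary:
    """Assemble the cohort co-mutation matrix from nomination reports.

    One column per patient (every patient with an HRD call appears); gene
    rows are grouped by category; cells carry the retention type, 'point-hit'
    or 'germline'.
    """
    patients = sorted(hrd_calls)
    hrd_rows = pd.DataFrame(
        {
            pid: [
                _tick(hrd_calls[pid].sig3_present),
                _tick(hrd_calls[pid].scar_positive),
                _tick(hrd_calls[pid].consensus_positive),
            ]
            for pid in patients
        },
        index=["Sig3", "Scar", "Consensus"],
    )

    category_of: dict[str, str] = {}
    cells: dict[str, dict[str, str]] = {}
    for r in reports:
        if not r.gene:
            continue
        category_of[r.gene] = r.category
        code = "germline"
        if r.retention != "none":
            code = r.retention
        elif r.somatic_point_hit is not None:
            code = "point-hit"
        cells.setdefault(r.gene, {})[r.patient_id] = code
    rank = {c: i for i, c in enumerate(category_order)}
    genes = sorted(
        cells, key=lambda g: (rank.get(category_of.get(g, ""), 99), g)
    )
    matrix = pd.DataFrame(
        [[cells[g].get(pid, "") for pid in patients] for g in genes],
        index=genes,
        columns=patients,
    )
    return CoMutationSummary(matrix=matrix, hrd_rows=hrd_rows,
                             category_of=category_of)


def _tick(flag: bool | None) -> str:
    if flag is None:
        return "no-call"
    return "positive" if flag else "negative"
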