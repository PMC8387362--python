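"""Pipeline configuration: every threshold in one serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .filters import GermlineQualityThresholds, SomaticFilterThresholds

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the analysis, with the study defaults.

    Thresholds: germline quality (depth >= 5, alt reads >= 2, heterozygote
    allelic-fraction window, mapping quality >= 30), population AF < 0.01,
    predictor quorum 4 of 8, somatic depth >= 10 with the strand-bias test,
    allelic-imbalance p <= 0.05, scar sum >= 42, Signature-3 caller
    calibrated at 5% false-positive rate.
    """

    # germline quality (rules i-iv)
    germline_min_depth: int = 5
    germline_min_alt_reads: int = 2
    germline_af_low: float = 0.35
    germline_af_high: float = 0.65
    germline_min_mapping_quality: float = 30.0
    # candidate selection
    population_af_threshold: float = 0.01
    predictor_quorum: int = 4
    # somatic filters
    somatic_min_depth: int = 10
    strand_bias_p: float = 0.01
    strand_bias_min_alt: int = 6
    # second hit
    ai_p_cutoff: float = 0.05
    continuity: bool = False
    # HRD
    scar_threshold: int = 42
    hrd_loh_min_length: int = 15_000_000
    lst_min_segment: int = 10_000_000
    lst_smoothing: int = 3_000_000
    sig3_fpr: float = 0.05
    sig3_min_mutations: int = 5
    sig3_calibration_sims: int = 1000
    require_consensus: bool = True
    caveat_genes: tuple[str, ...] = ("CHEK2",)
    # io
    input_dir: str = ""
    output_dir: str = ""
    signature_matrix_path: str = ""
    gene_lists_path: str = ""
    plot: bool = False
    seed: int = 0

    def germline_thresholds(self) -> GermlineQualityThresholds:
        return GermlineQualityThresholds(
            min_depth=self.germline_min_depth,
            min_alt_reads=self.germline_min_alt_reads,
            af_low=self.germline_af_low,
            af_high=self.germline_af_high,
            min_mapping_quality=self.germline_min_mapping_quality,
        )

    def somatic_thresholds(self) -> SomaticFilterThresholds:
        return SomaticFilterThresholds(
            strand_bias_p=self.strand_bias_p,
            strand_bias_min_alt=self.strand_bias_min_alt,
            min_depth=self.somatic_min_depth,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["caveat_genes"] = list(self.caveat_genes)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "caveat_genes" in data:
            data["caveat_genes"] = tuple(data["caveat_genes"])
        return cls(**data)
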