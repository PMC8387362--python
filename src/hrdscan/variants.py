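"""The variant observation record that flows through every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CONSEQUENCES",
    "TRUNCATING_CONSEQUENCES",
    "LOF_CONSEQUENCES",
    "CLINVAR_CLASSES",
    "PREDICTOR_NAMES",
    "VariantObservation",
]

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice",
    "synonymous",
    "other",
)
#: Truncating consequences (classified separately from missense).
TRUNCATING_CONSEQUENCES = frozenset({"nonsense", "frameshift"})
#: Loss-of-function consequences accepted as somatic second-hit point events.
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice"})

CLINVAR_CLASSES = (
    "Pathogenic",
    "Likely pathogenic",
    "VUS",
    "CIOP",
    "Likely benign",
    "Benign",
    "Unknown",
)

#: The eight in-silico deleteriousness predictors, in reporting order.
PREDICTOR_NAMES = (
    "SIFT",
    "PolyPhen2",
    "MutationTaster",
    "FATHM",
    "Provean",
    "MetaSVM",
    "MetaLR",
    "CADD",
)


@dataclass
class VariantObservation:
    """One germline or somatic variant with paired normal/tumor read counts.

    Coordinates are 1-based. ``predictor_calls`` holds up to eight boolean
    deleteriousness calls (``None`` = tool made no call). ``strand_alt_counts``
    is (forward, reverse) read support for the alternate allele;
    ``strand_ref_counts`` likewise for the reference allele when available.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    origin: str = "germline"  # germline | somatic
    gene_symbol: str = ""
    consequence: str = "other"
    germline_ref_count: int | None = None
    germline_alt_count: int | None = None
    tumor_ref_count: int | None = None
    tumor_alt_count: int | None = None
    mapping_quality: float | None = None
    strand_alt_counts: tuple[int, int] | None = None
    strand_ref_counts: tuple[int, int] | None = None
    population_af: float | None = None
    clinvar_class: str = "Unknown"
    acmg_class: str | None = None
    predictor_calls: tuple[bool | None, ...] = field(default_factory=tuple)
    context: str | None = None  # trinucleotide context, for catalogs
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.origin not in ("germline", "somatic"):
            raise ValueError(f"bad origin {self.origin!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"bad consequence {self.consequence!r}")
        for name in (
            "germline_ref_count",
            "germline_alt_count",
            "tumor_ref_count",
            "tumor_alt_count",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.predictor_calls) > len(PREDICTOR_NAMES):
            raise ValueError(
                f"at most {len(PREDICTOR_NAMES)} predictor calls allowed"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def germline_depth(self) -> int | None:
        if self.germline_ref_count is None or self.germline_alt_count is None:
            return None
        return self.germline_ref_count + self.germline_alt_count

    @property
    def tumor_depth(self) -> int | None:
        if self.tumor_ref_count is None or self.tumor_alt_count is None:
            return None
        return self.tumor_ref_count + self.tumor_alt_count

    @property
    def germline_af(self) -> float | None:
        d = self.germline_depth
        if d is None or d == 0:
            return None
        return self.germline_alt_count / d

    @property
    def tumor_af(self) -> float | None:
        d = self.tumor_depth
        if d is None or d == 0:
            return None
        return self.tumor_alt_count / d
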