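"""Synthetic tumor/normal cohort generator.

Every downstream stage is desk-testable against this generator, which
emulates the statistical structure the analysis assumes:

* beta-binomial read counts with one overdispersion knob (rho = 0
  degenerates to binomial); heterozygous sites are centred at an observed
  alt fraction slightly below 0.5 (reference-mapping bias);
* tumor allele fractions shifted by purity and the local allele-specific
  copy-number state;
* strand-skewed low-VAF C>T / G>A FFPE artifacts drawn from a recurrent
  hotspot pool, most of which is blacklisted by the simulated panel of
  normals;
* allele-specific segment profiles constructed to hit requested scar
  scores (HRD-LOH, LST, TAI) *exactly*, by composing three independent
  lesion units that each move exactly one score;
* 96-channel mutation catalogs drawn from signature mixtures with a
  controllable Signature-3 exposure;
* spiked "causal" patients: a rare heterozygous germline variant in a
  clinical-panel gene, a copy-neutral LOH second hit retaining the variant,
  a Signature-3-positive catalog and scar scores over the HRD threshold.

Per-patient random streams are spawned from the master seed with numpy's
``SeedSequence`` (patient i uses child i + 1; child 0 drives cohort-level
draws), so identical configurations yield identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genes import (
    GeneLists,
    placeholder_gene_lists,
    synthetic_gene_intervals,
)
from .genome import AlleleSpecificSegment, GenomeLayout, hg19_autosomes
from .scars import scar_scores
from .signatures import (
    CHANNELS_96,
    MutationCatalog,
    SignatureMatrix,
    synthetic_signature_matrix,
)
from .variants import VariantObservation

__all__ = [
    "SimulationConfig",
    "PatientTruth",
    "GroundTruth",
    "Cohort",
    "ScarTargetInfeasibleError",
    "simulate_read_counts",
    "expected_tumor_vaf",
    "simulate_tumor_counts_at_locus",
    "simulate_catalog",
    "simulate_segments",
    "inject_ffpe_artifacts",
    "spike_causal_scenario",
    "simulate_cohort",
]


class ScarTargetInfeasibleError(ValueError):
    """Requested scar scores cannot be placed on the genome layout."""


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Depth defaults follow the study scale (mean exome coverage ~141X);
    ``het_af`` is the mean *observed* alt fraction at heterozygous sites
    (below 0.5 because of reference-mapping bias); ``ffpe_artifact_rate`` is
    artifacts per Mb of exome territory; ``sig3_exposure`` and
    ``spike_scar_targets`` are the tumor phenotype given to spiked causal
    patients.
    """

    n_patients: int = 20
    mean_depth_normal: float = 141.0
    mean_depth_tumor: float = 141.0
    overdispersion: float = 0.01  # beta-binomial rho
    tumor_purity: float = 0.6
    ffpe_artifact_rate: float = 1.0  # per Mb
    exome_mb: float = 30.0
    sig3_exposure: float = 0.6
    n_somatic_snvs: int = 100
    causal_fraction: float = 0.1
    het_af: float = 0.47
    n_background_germline: int = 8
    spike_scar_targets: tuple[int, int, int] = (24, 12, 8)
    n_artifact_hotspots: int = 400
    pon_hotspot_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_somatic_snvs < 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.overdispersion < 1):
            raise ValueError("overdispersion rho must be in [0, 1)")
        if not (0 < self.tumor_purity <= 1):
            raise ValueError("tumor_purity must be in (0, 1]")
        for name in ("sig3_exposure", "causal_fraction", "het_af",
                     "pon_hotspot_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ffpe_artifact_rate < 0:
            raise ValueError("ffpe_artifact_rate must be >= 0")
        if min(self.mean_depth_normal, self.mean_depth_tumor) <= 0:
            raise ValueError("mean depths must be positive")

    @property
    def n_spiked(self) -> int:
        return int(round(self.causal_fraction * self.n_patients))


@dataclass
class PatientTruth:
    patient_id: str
    causal_gene: str | None = None
    loh_type: str | None = None  # true LOH type at the spiked locus
    sig3_exposure: float = 0.0
    scar: tuple[int, int, int] = (0, 0, 0)
    artifact_keys: set = field(default_factory=set)
    true_somatic_keys: set = field(default_factory=set)


@dataclass
class GroundTruth:
    """Per-patient truth; kept out of every emitted data table."""

    patients: dict[str, PatientTruth] = field(default_factory=dict)

    @property
    def spiked_patients(self) -> list[str]:
        return [p for p, t in self.patients.items() if t.causal_gene]

    def to_json(self) -> str:
        payload = {}
        for pid, t in self.patients.items():
            payload[pid] = {
                "causal_gene": t.causal_gene,
                "loh_type": t.loh_type,
                "sig3_exposure": t.sig3_exposure,
                "scar": list(t.scar),
                "artifact_keys": sorted(map(list, t.artifact_keys)),
                "true_somatic_keys": sorted(map(list, t.true_somatic_keys)),
            }
        return json.dumps(payload, indent=1)


def _beta_binomial(
    rng: np.random.Generator, depth: int, p: float, rho: float
) -> int:
    """Alt count ~ beta-binomial(depth, p, rho); rho=0 is binomial."""
    if depth == 0:
        return 0
    if p <= 0.0:
        return 0
    if p >= 1.0:
        return depth
    if rho == 0.0:
        return int(rng.binomial(depth, p))
    nu = 1.0 / rho - 1.0
    q = rng.beta(p * nu, (1.0 - p) * nu)
    return int(rng.binomial(depth, q))


def _rng_of(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_read_counts(
    allele_fraction: float,
    depth: int,
    overdispersion: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[int, int]:
    """Draw ``(ref_count, alt_count)`` summing to ``depth``."""
    if not (0.0 <= allele_fraction <= 1.0):
        raise ValueError("allele_fraction must be in [0, 1]")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if not (0.0 <= overdispersion < 1.0):
        raise ValueError("overdispersion rho must be in [0, 1)")
    rng = _rng_of(seed)
    alt = _beta_binomial(rng, depth, allele_fraction, overdispersion)
    return depth - alt, alt


def expected_tumor_vaf(
    purity: float,
    total_cn: int,
    variant_cn: int,
    germline_af: float = 0.5,
) -> float:
    """Expected tumor alt fraction at a germline heterozygous site.

    With one variant copy in normal cells, ``(purity*variant_cn +
    (1-purity)*1) / (purity*total_cn + (1-purity)*2)``; ``germline_af``
    applies the observed heterozygote bias as an odds rescaling (0.5 keeps
    the raw value).
    """
    if variant_cn > total_cn:
        raise ValueError("variant_cn cannot exceed total_cn")
    if total_cn < 0 or variant_cn < 0:
        raise ValueError("copy numbers must be non-negative")
    denom = purity * total_cn + (1 - purity) * 2
    if denom == 0:
        return 0.0
    raw = (purity * variant_cn + (1 - purity) * 1) / denom
    if germline_af == 0.5 or raw in (0.0, 1.0):
        return raw
    k = germline_af / (1 - germline_af)
    return k * raw / (k * raw + (1 - raw))


def simulate_tumor_counts_at_locus(
    germline_af: float,
    purity: float,
    total_cn: int,
    variant_cn: int,
    depth: int,
    seed: int | np.random.Generator = 0,
    overdispersion: float = 0.0,
) -> tuple[int, int]:
    """Tumor ``(ref, alt)`` counts at a germline heterozygous site under the
    local copy-number state; counts drawn as in :func:`simulate_read_counts`."""
    if not (0.0 <= purity <= 1.0):
        raise ValueError("purity must be in [0, 1]")
    vaf = expected_tumor_vaf(purity, total_cn, variant_cn, germline_af)
    return simulate_read_counts(vaf, depth, overdispersion, seed)


def simulate_catalog(
    exposures: Mapping[str, float] | Sequence[float],
    n_mutations: int,
    signature_matrix: SignatureMatrix,
    seed: int | np.random.Generator = 0,
) -> MutationCatalog:
    """Multinomial catalog draw from a signature mixture.

    ``exposures`` must sum to 1 (tolerance 1e-8); the catalog sums to
    ``n_mutations``.
    """
    if isinstance(exposures, Mapping):
        e = np.array([exposures.get(n, 0.0) for n in signature_matrix.names])
    else:
        e = np.asarray(exposures, dtype=float)
        if e.shape != (len(signature_matrix.names),):
            raise ValueError("exposure vector length must match signatures")
    if (e < 0).any():
        raise ValueError("exposures must be non-negative")
    if abs(e.sum() - 1.0) > 1e-8:
        raise ValueError(f"exposures must sum to 1, got {e.sum()!r}")
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    rng = _rng_of(seed)
    probs = signature_matrix.values @ e
    probs = probs / probs.sum()
    counts = rng.multinomial(n_mutations, probs) if n_mutations else np.zeros(96)
    return MutationCatalog(np.asarray(counts, dtype=float))


# --- scar-target segment construction ------------------------------------
#
# Three lesion units, each moving exactly one score when separated from any
# other non-diploid segment by >= 10 Mb of heterozygous diploid genome:
#
#   TAI unit     8 Mb (3,1) at a telomere (AI, sub-LST length, minor > 0)
#   LST unit     12 Mb (4,2) at a telomere (balanced duplication: one
#                qualifying breakpoint against the >= 10 Mb diploid neighbor)
#   HRD-LOH unit interstitial [4 Mb (3,1)][18 Mb (1,0)][4 Mb (3,1)]: the
#                4 Mb buffers survive 3 Mb smoothing but block LST pairing
#
# An interior LST unit (12 Mb (4,2) flanked by >= 10 Mb diploid) adds two
# breakpoints and mops up LST parity when telomere slots run out.

_TEL_AI_LEN = 8_000_000
_TEL_LST_LEN = 12_000_000
_BUFFER_LEN = 4_000_000
_LOH_CORE_LEN = 18_000_000
_INT_LST_LEN = 12_000_000
_UNIT_GAP = 10_000_000
_INTERIOR_START = 30_000_000  # clear of telomere units and the gene zone


def _chrom_capacity(length: int) -> tuple[int, int]:
    lo = _INTERIOR_START
    hi = length - _TEL_LST_LEN - _UNIT_GAP
    return lo, hi


def simulate_segments(
    target_scores: tuple[int, int, int],
    genome_layout: GenomeLayout | None = None,
    seed: int | np.random.Generator = 0,
    exclude_chroms: Iterable[str] = (),
) -> list[AlleleSpecificSegment]:
    """Build an allele-specific segment profile whose computed scar scores
    equal ``target_scores = (hrd_loh, lst, tai)`` exactly.

    The profile tiles every chromosome of the layout; unused genome is
    diploid heterozygous (2,1). Raises
    :class:`ScarTargetInfeasibleError` when the targets cannot be placed.
    The construction is deterministic; ``seed`` is accepted for interface
    symmetry.
    """
    layout = genome_layout or hg19_autosomes()
    h_target, l_target, t_target = target_scores
    if min(h_target, l_target, t_target) < 0:
        raise ScarTargetInfeasibleError("scar targets must be non-negative")
    excluded = set(exclude_chroms)
    chroms = [c for c in layout.chromosomes if c.name not in excluded]
    if not chroms:
        raise ScarTargetInfeasibleError("no chromosomes available")

    # (chrom, interval, state) placements
    placements: list[tuple[str, int, int, int, int]] = []

    # telomere slots: (chrom, side); p side requires the unit to end before
    # the centromere for the TAI unit
    tel_slots: list[tuple] = []
    for c in chroms:
        tel_slots.append((c, "p"))
        tel_slots.append((c, "q"))

    def place_telomeric(c, side: str, length: int, total: int, minor: int):
        if side == "p":
            placements.append((c.name, 1, length, total, minor))
        else:
            placements.append((c.name, c.length - length + 1, c.length, total, minor))

    # TAI units first (the p-side must not cross the centromere)
    t_left = t_target
    for slot in list(tel_slots):
        if t_left == 0:
            break
        c, side = slot
        if side == "p" and _TEL_AI_LEN >= c.centromere:
            continue
        if side == "q" and c.length - _TEL_AI_LEN <= c.centromere:
            continue
        place_telomeric(c, side, _TEL_AI_LEN, 3, 1)
        tel_slots.remove(slot)
        t_left -= 1
    if t_left:
        raise ScarTargetInfeasibleError(
            f"cannot place {t_target} TAI units on this layout"
        )

    # telomeric LST units
    l_left = l_target
    for slot in list(tel_slots):
        if l_left == 0:
            break
        c, side = slot
        place_telomeric(c, side, _TEL_LST_LEN, 4, 2)
        tel_slots.remove(slot)
        l_left -= 1

    # interior placements: HRD-LOH units and (if needed) interior LST pairs
    interior_units: list[tuple[int, tuple[int, int, int] | None]] = []
    # each entry: (width, list of (offset, length, total, minor))
    loh_unit = (
        2 * _BUFFER_LEN + _LOH_CORE_LEN,
        [
            (0, _BUFFER_LEN, 3, 1),
            (_BUFFER_LEN, _LOH_CORE_LEN, 1, 0),
            (_BUFFER_LEN + _LOH_CORE_LEN, _BUFFER_LEN, 3, 1),
        ],
    )
    int_lst_unit = (_INT_LST_LEN, [(0, _INT_LST_LEN, 4, 2)])
    queue: list[tuple[int, list]] = [loh_unit] * h_target
    if l_left:
        if l_left % 2 == 1:
            raise ScarTargetInfeasibleError(
                "odd LST remainder with no telomere slot left"
            )
        queue += [int_lst_unit] * (l_left // 2)

    cursors = {c.name: _chrom_capacity(c.length)[0] for c in chroms}
    limits = {c.name: _chrom_capacity(c.length)[1] for c in chroms}
    ci = 0
    while queue:
        width, parts = queue[0]
        placed = False
        for _ in range(len(chroms)):
            c = chroms[ci % len(chroms)]
            ci += 1
            start = cursors[c.name]
            if start + width - 1 <= limits[c.name]:
                for off, length, total, minor in parts:
                    placements.append(
                        (c.name, start + off, start + off + length - 1, total, minor)
                    )
                cursors[c.name] = start + width + _UNIT_GAP
                placed = True
                break
        if not placed:
            raise ScarTargetInfeasibleError(
                "genome layout exhausted while placing scar units"
            )
        queue.pop(0)

    # tile each chromosome: diploid heterozygous between placements
    segments: list[AlleleSpecificSegment] = []
    by_chrom: dict[str, list[tuple[int, int, int, int]]] = {
        c.name: [] for c in layout.chromosomes
    }
    for chrom, start, end, total, minor in placements:
        by_chrom[chrom].append((start, end, total, minor))
    for c in layout.chromosomes:
        parts = sorted(by_chrom[c.name])
        pos = 1
        for start, end, total, minor in parts:
            if start > pos:
                segments.append(AlleleSpecificSegment(c.name, pos, start - 1, 2, 1))
            segments.append(AlleleSpecificSegment(c.name, start, end, total, minor))
            pos = end + 1
        if pos <= c.length:
            segments.append(AlleleSpecificSegment(c.name, pos, c.length, 2, 1))

    got = scar_scores(segments, layout)
    if got.as_tuple() != (h_target, l_target, t_target):
        raise ScarTargetInfeasibleError(
            f"constructed profile scores {got.as_tuple()} != targets "
            f"{(h_target, l_target, t_target)}"
        )
    return segments


# --- FFPE artifacts --------------------------------------------------------

_CT_CONTEXTS = tuple(f"{f}C{t}" for f in "ACGT" for t in "ACGT")


def _make_hotspots(
    rng: np.random.Generator, n: int, layout: GenomeLayout
) -> list[dict]:
    """A pool of recurrent formalin-damage sites (fixed allele and strand)."""
    lengths = np.array([c.length for c in layout.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    hotspots = []
    for _ in range(n):
        ci = rng.choice(len(lengths), p=probs)
        chrom = layout.names[ci]
        pos = int(rng.integers(1, layout.chromosomes[ci].length + 1))
        on_g = bool(rng.random() < 0.5)  # reported as G>A on the other strand
        context = _CT_CONTEXTS[rng.integers(len(_CT_CONTEXTS))]
        hotspots.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "G" if on_g else "C",
                "alt": "A" if on_g else "T",
                "context": context if not on_g else _revcomp3(context),
                "skew_forward": bool(rng.random() < 0.5),
            }
        )
    return hotspots


def _revcomp3(ctx: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(ctx))


def inject_ffpe_artifacts(
    somatic_variants: list[VariantObservation],
    rate: float,
    seed: int | np.random.Generator = 0,
    hotspots: list[dict] | None = None,
    exome_mb: float = 30.0,
    mean_depth: float = 141.0,
    patient_id: str = "",
) -> tuple[list[VariantObservation], set]:
    """Append strand-skewed low-VAF C>T / G>A artifact calls.

    ``rate`` is artifacts per Mb over ``exome_mb`` of territory. Every
    injected record is C>T or G>A with >= 90% of alternate reads on one
    strand. Returns the augmented list and the set of injected keys;
    ``rate=0`` returns the input untouched.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return somatic_variants, set()
    rng = _rng_of(seed)
    if hotspots is None:
        hotspots = _make_hotspots(rng, 400, hg19_autosomes())
    n = int(rng.poisson(rate * exome_mb))
    out = list(somatic_variants)
    keys = set()
    for _ in range(n):
        h = hotspots[int(rng.integers(len(hotspots)))]
        depth = max(int(rng.poisson(mean_depth)), 12)
        vaf = rng.uniform(0.05, 0.15)
        alt = max(int(rng.binomial(depth, vaf)), 6)
        minority = min(int(rng.binomial(alt, 0.03)), alt // 10)
        major = alt - minority
        fwd, rev = (major, minority) if h["skew_forward"] else (minority, major)
        ref_reads = depth - alt
        ref_fwd = int(rng.binomial(ref_reads, 0.5)) if ref_reads else 0
        v = VariantObservation(
            chrom=h["chrom"],
            pos=h["pos"],
            ref_allele=h["ref"],
            alt_allele=h["alt"],
            origin="somatic",
            gene_symbol="",
            consequence="other",
            tumor_ref_count=ref_reads,
            tumor_alt_count=alt,
            strand_alt_counts=(fwd, rev),
            strand_ref_counts=(ref_fwd, ref_reads - ref_fwd),
            mapping_quality=60.0,
            context=h["context"],
            patient_id=patient_id,
        )
        out.append(v)
        keys.add(v.key)
    return out, keys


# --- spiked causal scenario ------------------------------------------------


def spike_causal_scenario(
    patient_id: str,
    gene: str,
    config: SimulationConfig,
    gene_intervals: Mapping[str, tuple[str, int, int]],
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> tuple[VariantObservation, list[AlleleSpecificSegment], PatientTruth]:
    """A causal patient: rare heterozygous germline variant in ``gene``,
    CN-LOH second hit retaining the variant, HRD-range scar profile.

    Returns the germline variant, the full segment profile and the truth
    entry (Signature-3 exposure is recorded; the catalog itself is drawn by
    the cohort loop).
    """
    if gene not in gene_intervals:
        raise ValueError(f"gene {gene!r} has no interval")
    chrom, g_start, g_end = gene_intervals[gene]
    gene_mid = (g_start + g_end) // 2

    segments = simulate_segments(
        config.spike_scar_targets, layout, exclude_chroms=(chrom,)
    )
    # CN-LOH lesion over the gene: 12 Mb (2,0) core with 4 Mb (3,1) buffers —
    # contributes nothing to any scar score (sub-HRD-LOH length, sub-LST
    # neighbors, interstitial)
    core_half = 6_000_000
    c_start, c_end = gene_mid - core_half, gene_mid + core_half - 1
    b1 = c_start - _BUFFER_LEN
    b2 = c_end + _BUFFER_LEN
    chrom_len = layout.length(chrom)
    spike = [
        AlleleSpecificSegment(chrom, 1, b1 - 1, 2, 1),
        AlleleSpecificSegment(chrom, b1, c_start - 1, 3, 1),
        AlleleSpecificSegment(chrom, c_start, c_end, 2, 0),
        AlleleSpecificSegment(chrom, c_end + 1, b2, 3, 1),
        AlleleSpecificSegment(chrom, b2 + 1, chrom_len, 2, 1),
    ]
    segments = [s for s in segments if s.chrom != chrom] + spike

    g_depth = max(int(rng.poisson(config.mean_depth_normal)), 1)
    g_ref, g_alt = simulate_read_counts(
        config.het_af, g_depth, config.overdispersion, rng
    )
    t_depth = max(int(rng.poisson(config.mean_depth_tumor)), 1)
    t_ref, t_alt = simulate_tumor_counts_at_locus(
        config.het_af,
        config.tumor_purity,
        total_cn=2,
        variant_cn=2,
        depth=t_depth,
        seed=rng,
        overdispersion=config.overdispersion,
    )
    variant = VariantObservation(
        chrom=chrom,
        pos=gene_mid,
        ref_allele="C",
        alt_allele="T",
        origin="germline",
        gene_symbol=gene,
        consequence="missense",
        germline_ref_count=g_ref,
        germline_alt_count=g_alt,
        tumor_ref_count=t_ref,
        tumor_alt_count=t_alt,
        mapping_quality=60.0,
        population_af=1e-4,
        clinvar_class="VUS",
        predictor_calls=(True, True, True, True, True, True, False, False),
        context="ACA",
        patient_id=patient_id,
    )
    truth = PatientTruth(
        patient_id=patient_id,
        causal_gene=gene,
        loh_type="CN-LOH",
        sig3_exposure=config.sig3_exposure,
        scar=tuple(scar_scores(segments, layout).as_tuple()),
    )
    return variant, segments, truth


# --- full cohort -----------------------------------------------------------


@dataclass
class Cohort:
    """An in-memory synthetic cohort plus its (non-emitted) ground truth."""

    config: SimulationConfig
    germline: list[VariantObservation]
    somatic: list[VariantObservation]
    segments: dict[str, list[AlleleSpecificSegment]]
    pon: set
    gene_lists: GeneLists
    gene_intervals: dict[str, tuple[str, int, int]]
    truth: GroundTruth
    layout: GenomeLayout
    signature_matrix: SignatureMatrix

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.segments)


_CONSEQ_BACKGROUND = ("missense", "synonymous", "nonsense", "frameshift",
                      "splice", "other")
_CONSEQ_P = (0.55, 0.15, 0.05, 0.05, 0.05, 0.15)

_PYRIMIDINE_OF = {"C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
                  "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G")}


def _channel_record(channel: str, rng: np.random.Generator):
    """(ref, alt, context) for a channel, randomly strand-flipped."""
    five, rest = channel[0], channel[2:]
    sub, three = rest[:3], rest[-1]
    ref, alt = _PYRIMIDINE_OF[sub]
    context = f"{five}{ref}{three}"
    if rng.random() < 0.5:
        context = _revcomp3(context)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref, alt = comp[ref], comp[alt]
    return ref, alt, context


def _background_germline(
    patient_id: str,
    n: int,
    config: SimulationConfig,
    gene_pool: list[str],
    gene_intervals: Mapping[str, tuple[str, int, int]],
    segments: list[AlleleSpecificSegment],
    rng: np.random.Generator,
) -> list[VariantObservation]:
    out = []
    genes = rng.choice(len(gene_pool), size=min(n, len(gene_pool)), replace=False)
    for gi in genes:
        gene = gene_pool[int(gi)]
        chrom, g_start, g_end = gene_intervals[gene]
        pos = (g_start + g_end) // 2
        consequence = str(rng.choice(_CONSEQ_BACKGROUND, p=_CONSEQ_P))
        u = rng.random()
        if u < 0.2:
            pop_af = float(rng.uniform(0.01, 0.2))  # common: frequency-filtered
        else:
            pop_af = float(10 ** rng.uniform(-6, -3))
        u = rng.random()
        if u < 0.15:
            clinvar = str(rng.choice(["Benign", "Likely benign"]))
        elif u < 0.45:
            clinvar = str(rng.choice(["VUS", "CIOP"]))
        else:
            clinvar = "Unknown"
        predictors = tuple(bool(b) for b in rng.random(8) < 0.35)
        mq = 60.0 if rng.random() > 0.05 else 20.0
        depth_mean = config.mean_depth_normal if rng.random() > 0.05 else 4.0
        g_depth = max(int(rng.poisson(depth_mean)), 0)
        g_ref, g_alt = simulate_read_counts(
            config.het_af, g_depth, config.overdispersion, rng
        )
        seg = next(
            (s for s in segments if s.contains(chrom, pos)), None
        )
        total_cn, minor_cn = (seg.total_cn, seg.minor_cn) if seg else (2, 1)
        # the variant allele is equally likely on either haplotype
        variant_cn = minor_cn if rng.random() < 0.5 else total_cn - minor_cn
        t_depth = max(int(rng.poisson(config.mean_depth_tumor)), 1)
        t_ref, t_alt = simulate_tumor_counts_at_locus(
            config.het_af,
            config.tumor_purity,
            total_cn=total_cn,
            variant_cn=variant_cn,
            depth=t_depth,
            seed=rng,
            overdispersion=config.overdispersion,
        )
        out.append(
            VariantObservation(
                chrom=chrom,
                pos=pos,
                ref_allele="G",
                alt_allele="A",
                origin="germline",
                gene_symbol=gene,
                consequence=consequence,
                germline_ref_count=g_ref,
                germline_alt_count=g_alt,
                tumor_ref_count=t_ref,
                tumor_alt_count=t_alt,
                mapping_quality=mq,
                population_af=pop_af,
                clinvar_class=clinvar,
                predictor_calls=predictors,
                context="AGA",
                patient_id=patient_id,
            )
        )
    return out


def _true_somatic(
    patient_id: str,
    n: int,
    exposures: np.ndarray,
    config: SimulationConfig,
    matrix: SignatureMatrix,
    layout: GenomeLayout,
    segments: list[AlleleSpecificSegment],
    rng: np.random.Generator,
) -> list[VariantObservation]:
    probs = matrix.values @ exposures
    probs = probs / probs.sum()
    lengths = np.array([c.length for c in layout.chromosomes], dtype=float)
    chrom_p = lengths / lengths.sum()
    out = []
    channel_idx = rng.choice(96, size=n, p=probs)
    for k in range(n):
        ref, alt, context = _channel_record(CHANNELS_96[channel_idx[k]], rng)
        ci = int(rng.choice(len(lengths), p=chrom_p))
        chrom = layout.names[ci]
        pos = int(rng.integers(1, layout.chromosomes[ci].length + 1))
        seg = next((s for s in segments if s.contains(chrom, pos)), None)
        total_cn = seg.total_cn if seg else 2
        p = config.tumor_purity
        denom = p * total_cn + (1 - p) * 2
        vaf = p * 1.0 / denom if denom > 0 else 0.0
        t_depth = max(int(rng.poisson(config.mean_depth_tumor)), 1)
        t_ref, t_alt = simulate_read_counts(
            vaf, t_depth, config.overdispersion, rng
        )
        alt_fwd = int(rng.binomial(t_alt, 0.5)) if t_alt else 0
        ref_fwd = int(rng.binomial(t_ref, 0.5)) if t_ref else 0
        g_depth = max(int(rng.poisson(config.mean_depth_normal)), 1)
        out.append(
            VariantObservation(
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                origin="somatic",
                gene_symbol="",
                consequence=str(
                    rng.choice(
                        ["missense", "synonymous", "other"], p=[0.5, 0.3, 0.2]
                    )
                ),
                germline_ref_count=g_depth,
                germline_alt_count=0,
                tumor_ref_count=t_ref,
                tumor_alt_count=t_alt,
                strand_alt_counts=(alt_fwd, t_alt - alt_fwd),
                strand_ref_counts=(ref_fwd, t_ref - ref_fwd),
                mapping_quality=60.0,
                context=context,
                patient_id=patient_id,
            )
        )
    return out


def simulate_cohort(
    config: SimulationConfig,
    gene_lists: GeneLists | None = None,
    layout: GenomeLayout | None = None,
    signature_matrix: SignatureMatrix | None = None,
) -> Cohort:
    """Generate a full tumor/normal cohort under ``config``.

    ``round(causal_fraction * n_patients)`` patients receive the spiked
    causal scenario (germline BCSG missense + CN-LOH + Signature-3-positive,
    scar-positive tumor); the rest carry background variation only.
    """
    layout = layout or hg19_autosomes()
    gene_lists = gene_lists or placeholder_gene_lists()
    matrix = signature_matrix or synthetic_signature_matrix()
    gene_intervals = synthetic_gene_intervals(gene_lists, layout)

    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_patients + 1)
    cohort_rng = np.random.default_rng(children[0])

    hotspots = _make_hotspots(cohort_rng, config.n_artifact_hotspots, layout)
    pon = {
        (h["chrom"], h["pos"], h["ref"], h["alt"])
        for h in hotspots
        if cohort_rng.random() < config.pon_hotspot_fraction
    }

    spiked_idx = set(
        cohort_rng.choice(config.n_patients, size=config.n_spiked, replace=False)
        .tolist()
    )
    bcsg = sorted(gene_lists.bcsg)
    sig3_col = matrix.names.index(matrix.sig3_name)
    other_cols = [i for i in range(len(matrix.names)) if i != sig3_col]

    germline: list[VariantObservation] = []
    somatic: list[VariantObservation] = []
    segments: dict[str, list[AlleleSpecificSegment]] = {}
    truth = GroundTruth()

    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        rng = np.random.default_rng(children[i + 1])
        exposures = np.zeros(len(matrix.names))
        if i in spiked_idx:
            gene = bcsg[int(rng.integers(len(bcsg)))]
            variant, segs, patient_truth = spike_causal_scenario(
                pid, gene, config, gene_intervals, layout, rng
            )
            germline.append(variant)
            exposures[sig3_col] = config.sig3_exposure
            exposures[other_cols] = rng.dirichlet(np.ones(len(other_cols))) * (
                1 - config.sig3_exposure
            )
            spike_chrom = gene_intervals[gene][0]
        else:
            targets = (
                int(rng.integers(0, 3)),
                int(rng.integers(0, 3)),
                int(rng.integers(0, 3)),
            )
            segs = simulate_segments(targets, layout)
            patient_truth = PatientTruth(
                patient_id=pid,
                sig3_exposure=0.0,
                scar=tuple(scar_scores(segs, layout).as_tuple()),
            )
            exposures[other_cols] = rng.dirichlet(np.ones(len(other_cols)))
            spike_chrom = None

        gene_pool = [
            g
            for g in sorted(gene_lists.all_genes)
            if gene_intervals[g][0] != spike_chrom
        ]
        germline_bg = _background_germline(
            pid,
            config.n_background_germline,
            config,
            gene_pool,
            gene_intervals,
            segs,
            rng,
        )
        germline.extend(germline_bg)

        n_som = int(rng.poisson(config.n_somatic_snvs))
        som = _true_somatic(
            pid, n_som, exposures, config, matrix, layout, segs, rng
        )
        patient_truth.true_somatic_keys = {v.key for v in som}

        # a couple of germline leak-through calls (exercise somatic filter ii)
        leaks = rng.choice(len(germline_bg), size=min(2, len(germline_bg)),
                           replace=False)
        for li in leaks:
            g = germline_bg[int(li)]
            som.append(
                VariantObservation(
                    chrom=g.chrom,
                    pos=g.pos,
                    ref_allele=g.ref_allele,
                    alt_allele=g.alt_allele,
                    origin="somatic",
                    gene_symbol=g.gene_symbol,
                    consequence=g.consequence,
                    tumor_ref_count=g.tumor_ref_count,
                    tumor_alt_count=g.tumor_alt_count,
                    strand_alt_counts=(
                        (g.tumor_alt_count or 0) // 2,
                        (g.tumor_alt_count or 0) - (g.tumor_alt_count or 0) // 2,
                    ),
                    mapping_quality=60.0,
                    context="ACA",
                    patient_id=pid,
                )
            )

        som, artifact_keys = inject_ffpe_artifacts(
            som,
            config.ffpe_artifact_rate,
            rng,
            hotspots=hotspots,
            exome_mb=config.exome_mb,
            mean_depth=config.mean_depth_tumor,
            patient_id=pid,
        )
        patient_truth.artifact_keys = artifact_keys

        somatic.extend(som)
        segments[pid] = segs
        truth.patients[pid] = patient_truth

    return Cohort(
        config=config,
        germline=germline,
        somatic=somatic,
        segments=segments,
        pon=pon,
        gene_lists=gene_lists,
        gene_intervals=gene_intervals,
        truth=truth,
        layout=layout,
        signature_matrix=matrix,
    )
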