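"""Readers, writers and the file-based pipeline entry point.

Human-readable TSV mirrors are the first-class interchange format
(germline and somatic variant tables, SEG-like segment table, 96-channel
catalog table, gene lists, ground-truth JSON); a VCF dialect is supported
for variant tables through pysam. Coordinate conventions: variant tables
and SEG files are 1-based inclusive; BED input (gene intervals) is 0-based
half-open and converted at the boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import PipelineConfig
from .genes import GeneLists, read_gene_lists, write_gene_lists
from .genome import AlleleSpecificSegment
from .pipeline import PipelineResult, analyze_cohort
from .signatures import CHANNELS_96, SignatureMatrix, synthetic_signature_matrix
from .simulate import Cohort
from .variants import PREDICTOR_NAMES, VariantObservation

logger = logging.getLogger("hrdscan")

__all__ = [
    "read_variants",
    "write_variants_tsv",
    "write_variants_vcf",
    "read_segments",
    "write_segments",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_pon",
    "write_pon",
    "read_bed_intervals",
    "write_cohort",
    "read_cohort_inputs",
    "run_pipeline",
]

#: Column schema of the variant TSV tables (germline and somatic share it).
VARIANT_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "origin", "gene",
    "consequence", "g_ref", "g_alt", "t_ref", "t_alt", "alt_fwd", "alt_rev",
    "ref_fwd", "ref_rev", "mapping_quality", "population_af", "clinvar",
    "acmg", "predictors", "context",
]


def _predictors_str(calls: tuple) -> str:
    out = []
    for i in range(len(PREDICTOR_NAMES)):
        c = calls[i] if i < len(calls) else None
        out.append("." if c is None else ("1" if c else "0"))
    return ",".join(out)


def _parse_predictors(s) -> tuple:
    if s in (None, "", ".") or (isinstance(s, float) and pd.isna(s)):
        return ()
    out = []
    for tok in str(s).split(","):
        tok = tok.strip()
        out.append(None if tok == "." else tok == "1")
    return tuple(out)


def _opt_int(x):
    if x is None or (isinstance(x, float) and pd.isna(x)) or x == ".":
        return None
    return int(x)


def _opt_float(x):
    if x is None or (isinstance(x, float) and pd.isna(x)) or x == ".":
        return None
    return float(x)


def variants_to_frame(variants: Iterable[VariantObservation]) -> pd.DataFrame:
    rows = []
    for v in variants:
        fwd, rev = v.strand_alt_counts or (None, None)
        rfwd, rrev = v.strand_ref_counts or (None, None)
        rows.append(
            {
                "patient_id": v.patient_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "origin": v.origin,
                "gene": v.gene_symbol,
                "consequence": v.consequence,
                "g_ref": v.germline_ref_count,
                "g_alt": v.germline_alt_count,
                "t_ref": v.tumor_ref_count,
                "t_alt": v.tumor_alt_count,
                "alt_fwd": fwd,
                "alt_rev": rev,
                "ref_fwd": rfwd,
                "ref_rev": rrev,
                "mapping_quality": v.mapping_quality,
                "population_af": v.population_af,
                "clinvar": v.clinvar_class,
                "acmg": v.acmg_class,
                "predictors": _predictors_str(v.predictor_calls),
                "context": v.context,
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def _row_to_variant(row: dict, origin: str) -> VariantObservation:
    fwd, rev = _opt_int(row.get("alt_fwd")), _opt_int(row.get("alt_rev"))
    rfwd, rrev = _opt_int(row.get("ref_fwd")), _opt_int(row.get("ref_rev"))
    ctx = row.get("context")
    if isinstance(ctx, float) and pd.isna(ctx):
        ctx = None
    clinvar = row.get("clinvar")
    if clinvar in (None, "") or (isinstance(clinvar, float) and pd.isna(clinvar)):
        clinvar = "Unknown"
    acmg = row.get("acmg")
    if acmg in ("", ".") or (isinstance(acmg, float) and pd.isna(acmg)):
        acmg = None
    gene = row.get("gene")
    if gene is None or (isinstance(gene, float) and pd.isna(gene)):
        gene = ""
    return VariantObservation(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref_allele=str(row["ref"]),
        alt_allele=str(row["alt"]),
        origin=origin,
        gene_symbol=str(gene),
        consequence=str(row.get("consequence", "other")),
        germline_ref_count=_opt_int(row.get("g_ref")),
        germline_alt_count=_opt_int(row.get("g_alt")),
        tumor_ref_count=_opt_int(row.get("t_ref")),
        tumor_alt_count=_opt_int(row.get("t_alt")),
        mapping_quality=_opt_float(row.get("mapping_quality")),
        strand_alt_counts=(fwd, rev) if fwd is not None and rev is not None else None,
        strand_ref_counts=(rfwd, rrev) if rfwd is not None and rrev is not None else None,
        population_af=_opt_float(row.get("population_af")),
        clinvar_class=str(clinvar),
        acmg_class=acmg,
        predictor_calls=_parse_predictors(row.get("predictors")),
        context=str(ctx) if ctx is not None else None,
        patient_id=str(row.get("patient_id", "")),
    )


def write_variants_tsv(
    variants: Sequence[VariantObservation], path: str | Path
) -> None:
    df = variants_to_frame(variants)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_variants(
    path: str | Path, dialect: str = "tsv", origin: str | None = None
) -> tuple[list[VariantObservation], list[tuple[int, str]]]:
    """Load a variant table; returns ``(variants, bad_lines)``.

    ``dialect`` is ``tsv`` or ``vcf``; malformed rows are collected as
    (1-based line number, message) instead of aborting the load.
    """
    if dialect == "tsv":
        return _read_variants_tsv(path, origin)
    if dialect == "vcf":
        return _read_variants_vcf(path, origin)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf')")


def _read_variants_tsv(path, origin):
    df = pd.read_csv(
        path, sep="\t", na_values=["."], dtype={"chrom": str},
        float_precision="round_trip",
    )
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing column(s): {sorted(missing)}")
    variants, bad = [], []
    for i, row in enumerate(df.to_dict(orient="records")):
        row_origin = origin or row.get("origin", "germline")
        if isinstance(row_origin, float) and pd.isna(row_origin):
            row_origin = "germline"
        try:
            variants.append(_row_to_variant(row, str(row_origin)))
        except (ValueError, TypeError, KeyError) as exc:
            bad.append((i + 2, str(exc)))  # +2: header + 1-based
    return variants, bad


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient identifier">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=GREF,Number=1,Type=Integer,Description="Germline REF reads">
##INFO=<ID=GALT,Number=1,Type=Integer,Description="Germline ALT reads">
##INFO=<ID=TREF,Number=1,Type=Integer,Description="Tumor REF reads">
##INFO=<ID=TALT,Number=1,Type=Integer,Description="Tumor ALT reads">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##INFO=<ID=PAF,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar class">
##INFO=<ID=ACMG,Number=1,Type=String,Description="ACMG class">
##INFO=<ID=PRED,Number=1,Type=String,Description="Predictor calls 1/0/.">
##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide context">
##INFO=<ID=SAF,Number=2,Type=Integer,Description="ALT reads fwd,rev">
"""


def write_variants_vcf(
    variants: Sequence[VariantObservation], path: str | Path
) -> None:
    """Write a minimal annotated VCF (all annotations as INFO keys)."""
    contigs = sorted({v.chrom for v in variants})
    lines = [_VCF_HEADER.rstrip("\n")]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def _i(k, val):
        return None if val in (None, "") else f"{k}={val}"

    for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
        info = [
            _i("PATIENT", v.patient_id),
            _i("GENE", v.gene_symbol),
            _i("CSQ", v.consequence),
            _i("GREF", v.germline_ref_count),
            _i("GALT", v.germline_alt_count),
            _i("TREF", v.tumor_ref_count),
            _i("TALT", v.tumor_alt_count),
            _i("MQ", v.mapping_quality),
            _i("PAF", v.population_af),
            _i("CLNSIG", v.clinvar_class.replace(" ", "_") if v.clinvar_class else None),
            _i("ACMG", v.acmg_class.replace(" ", "_") if v.acmg_class else None),
            _i("PRED", _predictors_str(v.predictor_calls).replace(",", "")),
            _i("CTX", v.context),
        ]
        if v.strand_alt_counts is not None:
            info.append(f"SAF={v.strand_alt_counts[0]},{v.strand_alt_counts[1]}")
        info_s = ";".join(x for x in info if x) or "."
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t{info_s}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_variants_vcf(path, origin):
    import pysam

    variants, bad = [], []
    vf = pysam.VariantFile(str(path))

    def _get(rec_info, key, default=None):
        # pysam raises on INFO keys absent from the header
        try:
            return rec_info.get(key, default)
        except (KeyError, ValueError):
            return default

    for i, rec in enumerate(vf.fetch() if vf.index else vf):
        try:
            info = rec.info
            pred = str(_get(info, "PRED", "") or "")
            pred_tuple = tuple(
                None if ch == "." else ch == "1" for ch in pred
            )
            saf = _get(info, "SAF")
            clnsig = _get(info, "CLNSIG")
            acmg = _get(info, "ACMG")
            for alt in rec.alts or ():
                variants.append(
                    VariantObservation(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        origin=origin or "germline",
                        gene_symbol=str(_get(info, "GENE", "") or ""),
                        consequence=str(_get(info, "CSQ", "other") or "other"),
                        germline_ref_count=_get(info, "GREF"),
                        germline_alt_count=_get(info, "GALT"),
                        tumor_ref_count=_get(info, "TREF"),
                        tumor_alt_count=_get(info, "TALT"),
                        mapping_quality=_get(info, "MQ"),
                        strand_alt_counts=tuple(saf) if saf else None,
                        population_af=_get(info, "PAF"),
                        clinvar_class=(
                            str(clnsig).replace("_", " ") if clnsig else "Unknown"
                        ),
                        acmg_class=str(acmg).replace("_", " ") if acmg else None,
                        predictor_calls=pred_tuple,
                        context=str(_get(info, "CTX")) if _get(info, "CTX") else None,
                        patient_id=str(_get(info, "PATIENT", "") or ""),
                    )
                )
        except (ValueError, TypeError, KeyError) as exc:
            bad.append((i + 1, str(exc)))
    return variants, bad


# --- segments (SEG-like, 1-based inclusive) --------------------------------


def write_segments(
    segments_by_patient: dict[str, Sequence[AlleleSpecificSegment]],
    path: str | Path,
) -> None:
    rows = []
    for pid in sorted(segments_by_patient):
        for s in segments_by_patient[pid]:
            rows.append((pid, s.chrom, s.start, s.end, s.total_cn, s.minor_cn))
    pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "total_cn", "minor_cn"]
    ).to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> dict[str, list[AlleleSpecificSegment]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"sample", "chrom", "start", "end", "total_cn", "minor_cn"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"segment table missing column(s): {sorted(missing)}")
    out: dict[str, list[AlleleSpecificSegment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(
            AlleleSpecificSegment(
                str(row.chrom), int(row.start), int(row.end),
                int(row.total_cn), int(row.minor_cn),
            )
        )
    return out


def write_catalogs(catalogs: pd.DataFrame, path: str | Path) -> None:
    """Write a 96-row catalog table (channel label + one column per tumor)."""
    catalogs.to_csv(path, sep="\t", index_label="channel")


def read_catalogs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="channel")
    if list(df.index) != list(CHANNELS_96):
        raise ValueError("catalog table must contain the 96 channels in order")
    return df


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="channel")


def read_signature_matrix(
    path: str | Path, sig3_name: str = "Signature_3"
) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="channel")
    return SignatureMatrix(df, sig3_name=sig3_name)


def write_pon(pon: set, path: str | Path) -> None:
    rows = sorted(pon)
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def read_pon(path: str | Path) -> set:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples(index=False)
    }


def read_bed_intervals(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Gene intervals from BED (0-based half-open), converted to 1-based
    inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"],
        dtype={"chrom": str},
    )
    return {
        str(r.name): (str(r.chrom), int(r.start) + 1, int(r.end))
        for r in df.itertuples(index=False)
    }


# --- cohort emission and the file-based pipeline ---------------------------


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Emit a simulated cohort: variant tables, SEG table, catalog table,
    PoN, gene lists, signature matrix, config and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_variants_tsv(cohort.germline, outdir / "germline.tsv")
    write_variants_tsv(cohort.somatic, outdir / "somatic.tsv")
    write_segments(cohort.segments, outdir / "segments.seg")
    write_pon(cohort.pon, outdir / "pon.tsv")
    write_gene_lists(cohort.gene_lists, outdir / "gene_lists.tsv")
    write_signature_matrix(cohort.signature_matrix, outdir / "signatures.tsv")
    (outdir / "ground_truth.json").write_text(cohort.truth.to_json())
    import dataclasses
    import yaml

    (outdir / "simulation_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(cohort.config), sort_keys=False)
    )


def read_cohort_inputs(indir: str | Path):
    """Load the analysis inputs a simulated (or equivalent) cohort directory
    provides: germline/somatic variants, segments, PoN, gene lists, and the
    signature matrix (falling back to the built-in synthetic matrix)."""
    indir = Path(indir)
    germline, bad_g = read_variants(indir / "germline.tsv", "tsv", origin="germline")
    somatic, bad_s = read_variants(indir / "somatic.tsv", "tsv", origin="somatic")
    if bad_g or bad_s:
        logger.warning(
            "skipped malformed rows: %d germline, %d somatic", len(bad_g), len(bad_s)
        )
    segments = read_segments(indir / "segments.seg")
    pon = read_pon(indir / "pon.tsv") if (indir / "pon.tsv").exists() else set()
    gene_lists = read_gene_lists(indir / "gene_lists.tsv")
    sig_path = indir / "signatures.tsv"
    matrix = (
        read_signature_matrix(sig_path)
        if sig_path.exists()
        else synthetic_signature_matrix()
    )
    return germline, somatic, segments, pon, gene_lists, matrix


def _reports_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for r in result.reports:
        rows.append(
            {
                "patient_id": r.patient_id,
                "gene": r.gene,
                "verdict": r.verdict,
                "category": r.category,
                "consequence": r.consequence,
                "clinvar": r.clinvar_class,
                "acmg": r.acmg_class,
                "retention": r.retention,
                "p_value": r.p_value,
                "somatic_point_hit": (
                    "|".join(map(str, r.somatic_point_hit))
                    if r.somatic_point_hit
                    else ""
                ),
                "sig3_present": r.sig3_present,
                "scar_sum": r.scar_sum,
                "consensus_hrd": r.consensus_hrd,
                "caveat": r.caveat,
            }
        )
    return pd.DataFrame(rows)


def _second_hits_frame(result: PipelineResult) -> pd.DataFrame:
    """Second-hit table mirroring the per-variant evidence columns: gene,
    patient, retention type, the four read counts, p-value."""
    by_key = {(v.patient_id, v.key): v for v, _ in result.candidates}
    rows = []
    for (pid, key), sh in result.second_hits.items():
        v = by_key[(pid, key)]
        rows.append(
            {
                "gene": sh.gene,
                "patient_id": pid,
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "retention": sh.retention,
                "direction": sh.direction,
                "germline_ref": v.germline_ref_count,
                "germline_alt": v.germline_alt_count,
                "tumor_ref": v.tumor_ref_count,
                "tumor_alt": v.tumor_alt_count,
                "p_value": sh.p_value,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, calibration=None) -> PipelineResult:
    """File-based pipeline: read ``config.input_dir``, write every stage's
    outputs and removal logs under ``config.output_dir``."""
    if not config.input_dir:
        raise ValueError("config.input_dir is required")
    outdir = Path(config.output_dir or (Path(config.input_dir) / "results"))
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("thresholds: %s", config)
        germline, somatic, segments, pon, gene_lists, matrix = read_cohort_inputs(
            config.input_dir
        )
        if config.signature_matrix_path:
            matrix = read_signature_matrix(config.signature_matrix_path)
        if config.gene_lists_path:
            gene_lists = read_gene_lists(config.gene_lists_path)
        result = analyze_cohort(
            germline,
            somatic,
            segments,
            pon,
            gene_lists,
            config,
            signature_matrix=matrix,
            calibration=calibration,
        )

        variants_to_frame([v for v, _ in result.germline_removed]).assign(
            reason=[r for _, r in result.germline_removed]
        ).to_csv(outdir / "germline_removed.tsv", sep="\t", index=False, na_rep=".")
        variants_to_frame([v for v, _ in result.candidates]).assign(
            category=[c for _, c in result.candidates]
        ).to_csv(outdir / "candidates.tsv", sep="\t", index=False, na_rep=".")
        somatic_kept = [v for vs in result.somatic_kept.values() for v in vs]
        variants_to_frame(somatic_kept).to_csv(
            outdir / "somatic_kept.tsv", sep="\t", index=False, na_rep="."
        )
        somatic_removed = [
            (v, r) for vs in result.somatic_removed.values() for v, r in vs
        ]
        variants_to_frame([v for v, _ in somatic_removed]).assign(
            reason=[r for _, r in somatic_removed]
        ).to_csv(outdir / "somatic_removed.tsv", sep="\t", index=False, na_rep=".")

        hrd_rows = []
        for pid, h in sorted(result.hrd_calls.items()):
            hrd_rows.append(
                {
                    "patient_id": pid,
                    "sig3_present": h.sig3_present,
                    "sig3_exposure": h.sig3_exposure,
                    "sig3_score": h.sig3_score,
                    "hrd_loh": h.hrd_loh,
                    "lst": h.lst,
                    "tai": h.tai,
                    "scar_sum": h.scar_sum,
                    "scar_positive": h.scar_positive,
                    "consensus_positive": h.consensus_positive,
                    "flag": h.flag,
                }
            )
        pd.DataFrame(hrd_rows).to_csv(outdir / "hrd_calls.tsv", sep="\t", index=False)
        _second_hits_frame(result).to_csv(
            outdir / "second_hits.tsv", sep="\t", index=False
        )
        reports = _reports_frame(result)
        reports.to_csv(outdir / "reports.tsv", sep="\t", index=False)
        (outdir / "reports.json").write_text(
            json.dumps(reports.to_dict(orient="records"), indent=1, default=str)
        )
        result.comutation.to_tsv(outdir / "comutation.tsv")
        if config.plot:
            result.comutation.plot(outdir / "comutation.png")
        config.to_yaml(outdir / "pipeline_config.yaml")
        logger.info(
            "done: %d candidates, %d nominated",
            len(result.candidates),
            len(result.nominated()),
        )
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
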