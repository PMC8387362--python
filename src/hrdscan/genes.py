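"""Gene category lists and synthetic gene placement on the genome layout.

Four gene categories drive candidate interpretation: BCSG (clinical breast
cancer susceptibility panel genes), CSG (other cancer susceptibility genes),
DNA-repair genes, and C-HRG (candidate homologous-recombination genes).
A symbol on several lists resolves by the precedence
BCSG > CSG > DNA-repair > C-HRG; clinical panels dominate interpretation.

The true 594-gene C-HRG list is unpublished, so
:func:`placeholder_gene_lists` ships a *synthetic* stand-in with the
documented category sizes (20 / 147 / 103 / 594): the BCSG panel and a core
of well-known repair and susceptibility genes are real symbols, the
remainder are generated placeholders. It fixes the list *format* and sizes,
not the true membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genome import GenomeLayout, hg19_autosomes

__all__ = [
    "CATEGORY_PRECEDENCE",
    "GeneLists",
    "assign_gene_category",
    "placeholder_gene_lists",
    "synthetic_gene_intervals",
    "read_gene_lists",
    "write_gene_lists",
]

CATEGORY_PRECEDENCE = ("BCSG", "CSG", "DNA-repair", "C-HRG")

_BCSG_PANEL = (
    "ATM", "BARD1", "BRCA1", "BRCA2", "BRIP1", "CDH1", "CHEK2", "MLH1",
    "MRE11", "MSH2", "NBN", "NF1", "PALB2", "PTEN", "RAD50", "RAD51C",
    "RAD51D", "STK11", "TP53", "CDKN2A",
)
_CSG_CORE = (
    "APC", "FLCN", "FANCA", "GJB2", "VHL", "RB1", "RET", "MEN1", "SDHB",
    "SMAD4", "TSC1", "TSC2", "WT1", "MUTYH", "MSH6", "PMS2", "BMPR1A",
    "PTCH1", "SUFU", "DICER1",
)
_DNA_REPAIR_CORE = (
    "REV1", "LIG4", "POLQ", "XRCC1", "XRCC2", "XRCC3", "XRCC4", "ERCC1",
    "ERCC2", "ERCC3", "ERCC4", "ERCC5", "XPA", "XPC", "POLB", "POLE",
    "POLD1", "NEIL1", "NEIL2", "MBD4",
)
_CHRG_CORE = (
    "BRDT", "CABIN1", "EIF2D", "FCHO1", "NCOR1", "DNAH6", "TANGO2", "XIRP2",
    "RAD54L", "RAD54B", "RMI1", "RMI2", "TOP3A", "SPIDR", "SWSAP1", "ZSWIM7",
    "HELQ", "EXO1", "MCM8", "MCM9",
)


@dataclass(frozen=True)
class GeneLists:
    """Category membership sets with precedence-based lookup."""

    bcsg: frozenset[str]
    csg: frozenset[str]
    dna_repair: frozenset[str]
    c_hrg: frozenset[str]

    def category(self, symbol: str) -> str:
        if symbol in self.bcsg:
            return "BCSG"
        if symbol in self.csg:
            return "CSG"
        if symbol in self.dna_repair:
            return "DNA-repair"
        if symbol in self.c_hrg:
            return "C-HRG"
        return "other"

    @property
    def all_genes(self) -> frozenset[str]:
        return self.bcsg | self.csg | self.dna_repair | self.c_hrg

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat, genes in (
            ("BCSG", self.bcsg),
            ("CSG", self.csg),
            ("DNA-repair", self.dna_repair),
            ("C-HRG", self.c_hrg),
        ):
            rows += [(g, cat) for g in sorted(genes)]
        return pd.DataFrame(rows, columns=["symbol", "category"])


def assign_gene_category(symbol: str, gene_lists: GeneLists) -> str:
    """Category of ``symbol`` under BCSG > CSG > DNA-repair > C-HRG precedence;
    symbols on no list map to 'other'."""
    return gene_lists.category(symbol)


def _padded(core: tuple[str, ...], n: int, prefix: str) -> frozenset[str]:
    fillers = tuple(f"{prefix}{i:04d}" for i in range(1, n - len(core) + 1))
    return frozenset(core + fillers)


def placeholder_gene_lists(
    n_bcsg: int = 20, n_csg: int = 147, n_dna_repair: int = 103, n_chrg: int = 594
) -> GeneLists:
    """Synthetic gene category lists with the documented sizes (see module
    docstring); placeholder symbols are ``CSG####``, ``REP####``, ``HRG####``."""
    return GeneLists(
        bcsg=frozenset(_BCSG_PANEL[:n_bcsg]),
        csg=_padded(_CSG_CORE, n_csg, "CSG"),
        dna_repair=_padded(_DNA_REPAIR_CORE, n_dna_repair, "REP"),
        c_hrg=_padded(_CHRG_CORE, n_chrg, "HRG"),
    )


def synthetic_gene_intervals(
    gene_lists: GeneLists,
    layout: GenomeLayout | None = None,
    zone_start: int = 18_000_000,
    gene_length: int = 100_000,
    gene_spacing: int = 250_000,
) -> dict[str, tuple[str, int, int]]:
    """Deterministic synthetic genomic intervals for every listed gene.

    Genes are packed round-robin into one interstitial "gene zone" per
    chromosome beginning at ``zone_start`` bp — clear of telomeres so the
    cohort simulator can place scar lesions without touching gene loci. The
    placement is synthetic plumbing (real coordinates are irrelevant to the
    statistics); it is stable across calls for a fixed gene set.
    """
    layout = layout or hg19_autosomes()
    genes = sorted(gene_lists.all_genes)
    intervals: dict[str, tuple[str, int, int]] = {}
    n_chroms = len(layout.names)
    per_chrom_counter = [0] * n_chroms
    for i, gene in enumerate(genes):
        ci = i % n_chroms
        chrom = layout.names[ci]
        start = zone_start + per_chrom_counter[ci] * gene_spacing
        per_chrom_counter[ci] += 1
        intervals[gene] = (chrom, start, start + gene_length - 1)
    return intervals


def read_gene_lists(path: str | Path) -> GeneLists:
    """Read a two-column TSV (symbol, category) into :class:`GeneLists`."""
    df = pd.read_csv(path, sep="\t")
    missing = {"symbol", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"gene list TSV missing column(s): {sorted(missing)}")
    by_cat = {cat: frozenset(sub["symbol"]) for cat, sub in df.groupby("category")}
    return GeneLists(
        bcsg=by_cat.get("BCSG", frozenset()),
        csg=by_cat.get("CSG", frozenset()),
        dna_repair=by_cat.get("DNA-repair", frozenset()),
        c_hrg=by_cat.get("C-HRG", frozenset()),
    )


def write_gene_lists(gene_lists: GeneLists, path: str | Path) -> None:
    gene_lists.to_frame().to_csv(path, sep="\t", index=False)
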