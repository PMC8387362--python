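# hrdscan

Somatic **second-hit detection** and **homologous-recombination-deficiency
(HRD) consensus calling** for tumor/normal exome cohorts, aimed at one
question from hereditary breast-cancer genetics: when a multiple-case family
tests negative on the clinical gene panel, can the tumor itself tell us
whether an unrecognized HRD gene is responsible?

The package implements the tumor-suppressor two-hit logic end to end:

1. **Germline candidate selection.** Variants pass quality rules (depth ≥ 5,
   ALT reads ≥ 2, heterozygote allelic-fraction window, mapping quality
   ≥ 30), a population-frequency screen (max AF < 0.01), and routing by
   ClinVar/ACMG class, consequence and gene category (clinical BCSG panel,
   cancer susceptibility genes, DNA-repair genes, candidate HR genes).
   Missense variants outside the clinical panel additionally need a
   deleteriousness consensus from ≥ 4 of 8 in-silico predictors.
2. **Somatic filtering** tuned for FFPE material: exact binomial strand-bias
   test, matched-germline subtraction, panel-of-normals blacklist, depth ≥ 10.
3. **Second-hit detection.** For a germline candidate with counts
   (g_ref, g_alt) and tumor counts (t_ref, t_alt), Pearson's chi-squared test
   (1 df, no continuity correction) on the 2×2 table detects allelic
   imbalance; a significant (p ≤ 0.05), variant-retaining imbalance at a
   locus with minor copy number 0 is typed as DEL-LOH (total CN 1), CN-LOH
   (total CN 2) or DUP-LOH (total CN ≥ 3). Somatic loss-of-function point
   hits and purely somatic two-hit genes are also reported.
4. **HRD consensus.** Signature 3 presence is called by a calibrated
   likelihood-ratio test on the 96-channel trinucleotide catalog, and the
   genomic scar score is HRD-LOH + LST + TAI with tumors ≥ 42 scar-positive;
   a tumor is HRD only when *both* callers agree.
5. **Nomination.** A candidate behaves like a pathogenic HRD allele only
   with candidate + second hit + consensus-HRD tumor in the same patient
   and gene (genes such as CHEK2, whose biallelic loss is not
   Signature-3-associated, are never re-classified this way).

Because real patient-level data of this kind cannot be redistributed, the
package ships a **synthetic cohort generator** with full ground truth:
beta-binomial read counts, purity- and copy-number-shifted tumor allele
fractions, strand-skewed FFPE C>T artifacts from a recurrent hotspot pool,
allele-specific segment profiles constructed to hit requested scar scores
exactly, signature-mixture mutation catalogs, and spiked causal patients
(germline BCSG missense + CN-LOH second hit + Signature-3-positive,
scar-positive tumor).

## Worked example

```python
from hrdscan import (allelic_imbalance_test, retention_direction,
                     classify_loh_type, AlleleSpecificSegment,
                     VariantObservation, call_scar_hrd)

# germline 80 REF / 64 ALT, tumor 134 REF / 177 ALT at a missense locus
p = allelic_imbalance_test(80, 64, 134, 177)
print(f"p = {p:.6f}")                       # p = 0.013197
print(retention_direction(80, 64, 134, 177))  # variant-retained

v = VariantObservation(chrom="chr5", pos=112_175_240, ref_allele="C",
                       alt_allele="T", gene_symbol="APC",
                       consequence="missense",
                       germline_ref_count=80, germline_alt_count=64,
                       tumor_ref_count=134, tumor_alt_count=177)
seg = AlleleSpecificSegment("chr5", 100_000_000, 120_000_000,
                            total_cn=2, minor_cn=0)
print(classify_loh_type(v, [seg], p, "variant-retained"))  # CN-LOH
print(call_scar_hrd(20, 15, 8))             # True  (sum 43 >= 42)
```

The tumor allele fraction rose from 0.444 to 0.569 (p = 0.013), the locus
lost heterozygosity at total copy number 2, so the variant was retained
through a copy-neutral LOH event — a classic second hit.

Simulate and analyze a cohort from the shell:

```bash
hrdscan simulate --seed 5 --outdir cohort/
hrdscan run-all --indir cohort/ --seed 5
# -> 34 candidates; 2 second hits; 2 consensus-HRD tumors; 2 nominated
```

`cohort/results/` then holds the candidate list, removal logs with reason
codes, the second-hit table (gene, patient, retention type, the four read
counts, p-value), per-tumor HRD calls, the nomination reports and the
co-mutation summary. Subcommands `filter-germline`, `filter-somatic`,
`second-hit`, `hrd`, `nominate` and `report` run individual stages;
`--continuity` switches the chi-squared test to the Yates-corrected form and
`--config` accepts a YAML with every threshold.

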