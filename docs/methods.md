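# Methods

This note documents the statistical models, defaults, and design choices
behind hrdscan, and what the synthetic-cohort experiments do and do not
demonstrate about real data.

## The decision problem

In the two-hit tumor-suppressor model, a germline variant in an HRD gene
predisposes to breast cancer only if the tumor loses the remaining wild-type
allele and consequently loses homologous-recombination function. hrdscan
therefore re-classifies a germline candidate as behaving like a pathogenic
HRD allele only when three independent lines of evidence coincide in the
same patient and gene: a surviving germline candidate variant, a somatic
second hit, and a tumor-wide HRD phenotype called by two different readouts.
Each stage is described below.

## Allelic-imbalance test and LOH typing

The second-hit test is Pearson's chi-squared test (1 degree of freedom,
two-sided, **no continuity correction**) on the 2×2 table of germline
REF/ALT versus tumor REF/ALT read counts. The statistic is computed through
the expected-counts route, X² = Σ (O − E)²/E with E = outer(row, col)/N,
which is algebraically the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d));
the test suite verifies their agreement to 1e-12 relative error over an
exhaustive sweep of tables with all margins ≤ 50, and checks scipy's
implementation as an independent oracle. The uncorrected form was chosen
because it reproduces the majority of the published read-count worked
examples this package is validated against; a `continuity` option provides
the Yates-corrected test. Evidence is accepted at p ≤ 0.05, boundary
inclusive, with no multiple-testing correction (raw p-values are reported;
candidates per patient are few). Zero-margin tables are undefined and are
treated as no evidence, never as negative evidence.

A significant test converts to an LOH retention type only when the tumor
allele fraction *rose* (the variant allele was retained) and the
allele-specific copy-number segment covering the locus has minor copy
number 0: total copy number 1 is DEL-LOH (wild-type allele deleted), 2 is
CN-LOH (variant duplicated, wild-type lost), ≥ 3 is DUP-LOH. A homozygous
deletion (total 0) cannot retain the variant and maps to none. Segments
are consumed as input (1-based inclusive coordinates); inferring them from
reads is out of scope.

## Germline and somatic filters

Germline quality rules run in order — depth ≥ 5, ALT reads ≥ 2, allelic
fraction inside the heterozygote window, mapping quality ≥ 30 — and each
removal is tagged with the first failing rule. The default window is
**[0.35, 0.65], endpoints inclusive**. A narrower asymmetric window
([0.35, 0.5]) appears in some descriptions of this kind of filter, but it is
inconsistent with the read counts of validated heterozygous candidates
(observed germline allele fractions of retained variants reach 0.53), and at
~140X coverage it would discard roughly a third of true heterozygotes by
binomial noise alone; both endpoints are configurable, and the boundary
behavior of both windows is covered by tests. Absent population allele
frequencies are treated as 0 (novel variants are the search target) and the
frequency screen is strict: kept iff max AF < 0.01.

Candidate routing: ClinVar benign/likely-benign is dropped (ACMG class
substitutes when ClinVar is uninformative); truncating and splice variants
go to the master list; missense variants in clinical-panel (BCSG) genes are
kept regardless of predictor scores, elsewhere they need ≥ 4 of 8
deleteriousness calls (absent calls count in the denominator only). Gene
categories resolve by the precedence BCSG > CSG > DNA-repair > C-HRG. The
true candidate-HR-gene list is unpublished; the shipped lists carry the
documented category sizes (20/147/103/594) with a real clinical core and
synthetic placeholder symbols, fixing the format rather than the membership.

Somatic filters target FFPE artifacts: (i) strand bias — an exact two-sided
binomial test of the ALT-read forward/reverse split against the REF-read
strand ratio (0.5 when unavailable), removing at p < 0.01 with ≥ 6 ALT
reads; (ii) matched-germline subtraction; (iii) panel-of-normals blacklist;
(iv) tumor depth ≥ 10. The strand statistic is not prescribed anywhere
authoritative; the exact binomial was chosen as the simplest test with
correct small-count behavior, and both its threshold and the ALT-read floor
are configuration constants.

## Signature-3 caller

The 96-channel catalog uses the standard pyrimidine-strand convention
(purine-reference SNVs are reverse-complemented before binning). Exposures
to a fixed signature matrix are refit in two ways: non-negative least
squares on channel frequencies (reported exposures), and a multinomial
maximum-likelihood refit via EM multiplicative updates used for detection.
The detection statistic is the log-likelihood ratio of the ML refit with
versus without the Signature-3 column. Because the null distribution of
this boundary LRT is not chi-squared, the decision threshold is calibrated
by simulation: 1,000 Signature-3-free catalogs (flat Dirichlet mixtures of
the remaining signatures) per grid point over catalog sizes
{10, 25, 50, 100, 200, 400}, threshold = the empirical 95th percentile
(5% false-positive rate), interpolated linearly in log catalog size.
Catalogs under 5 SNVs yield a no-call, which propagates through the
consensus as a no-call rather than a negative. At 50-SNV catalogs the
calibrated caller detects exposure 0.5 in ≈ 97% of replicates and detection
is monotone in exposure.

COSMIC reference signatures cannot be redistributed with this package, so
the default matrix is **synthetic**: six deterministic v2-style columns
(Signature 1, 2, 3, 5, 8, 13 analogues) with the field-standard qualitative
structure — CpG-deamination C>T for 1, TpC APOBEC C>T/C>G for 2/13, broad
C>A for 8, T>C-tilted 5, and a near-flat Signature 3, the HRD hallmark.
Simulation and refitting share this matrix, so detection-rate results
characterize the caller's statistics, not the hardness of separating the
real COSMIC profiles; any 96×K matrix TSV can be supplied instead. Catalog
frequencies are not renormalized for genome trinucleotide composition
(simulation and fitting use the same convention, so no bias enters at this
scale).

## Genomic scar scores

The scar components follow the canonical published criteria behind the
additive scar index: HRD-LOH counts LOH segments longer than 15 Mb but
shorter than the whole chromosome; LST counts breakpoints between abutting
segments each ≥ 10 Mb with different allele-specific states, after
smoothing away segments < 3 Mb (the shortest sub-threshold segment is
absorbed into its longer neighbor, iteratively); TAI counts maximal
allelic-imbalance regions that reach a telomere without crossing the
centromere. All length constants are configurable. Scores are computed per
chromosome (not per arm), on profiles that tile each chromosome; segment
splitting that preserves copy states provably changes no score (property
tested). A tumor is scar-positive at HRD-LOH + LST + TAI ≥ 42, applied to
the raw (not ploidy-adjusted) sum, and the final HRD call is the logical
AND of the scar call and the Signature-3 call — mirroring the practice of
trusting only tumors positive by both readouts, since exome data are
marginal for large-scale copy-number events.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
defaults fixed once from the study scale it models:

* **Depth** — Poisson around 141X for normal and tumor (mean exome
  coverage of the motivating cohort).
* **Read counts** — beta-binomial with a single overdispersion knob
  ρ (default 0.01; ρ = 0 is binomial; variance n·p(1−p)(1+(n−1)ρ)).
* **Heterozygous sites** — mean *observed* ALT fraction 0.47, not 0.5,
  modeling reference-mapping bias; the observed germline fractions of
  validated heterozygous candidates in comparable data center near 0.466.
* **Tumor allele fractions** — expected VAF
  (φ·v + (1−φ))/(φ·t + 2(1−φ)) for a heterozygous site with variant copy
  number v on total t at purity φ (default 0.6, mid-range for FFPE breast
  tumors), with the heterozygote bias applied as an odds rescaling.
* **Somatic burden** — 100 SNVs/tumor (WES scale), contexts drawn from the
  signature mixture, positions uniform over the hg19 autosome layout.
* **FFPE artifacts** — 1 artifact/Mb over 30 Mb of territory, C>T (or G>A)
  at ≤ 15% VAF with ≥ 90% of ALT reads on one strand, drawn from a pool of
  400 recurrent hotspots of which 95% sit in the simulated panel of
  normals (recurrent formalin-damage sites are near-certain to appear in
  ≥ 2 of 47 same-protocol normals).
* **Scar profiles** — constructed to hit requested (HRD-LOH, LST, TAI)
  *exactly* by composing three orthogonal lesion units (a sub-LST telomeric
  AI unit, a balanced telomeric duplication for LST, a buffered interstitial
  LOH unit), each moving exactly one score; infeasible targets raise an
  explicit error.
* **Spiked causal patients** — round(causal_fraction·n) patients carry a
  rare heterozygous missense in a clinical-panel gene, a CN-LOH lesion
  retaining it (shaped to add nothing to any scar score), Signature-3
  exposure 0.6 and scar targets (24, 12, 8) = 44.
* **Reproducibility** — per-patient generators are spawned from the master
  seed with numpy `SeedSequence` (child 0 for cohort-level draws, child
  i+1 for patient i), so identical configurations are byte-identical on
  disk.

Gene coordinates are synthetic: genes are packed into one interstitial zone
per chromosome, placed so that scar lesions and gene loci never collide
except where a spike intends them to. Trinucleotide context is drawn from
the signature-implied channel rather than a reference FASTA — catalog
statistics are preserved without a sequence dependency, but the simulated
tables cannot be used for anything requiring true genomic context.

What passing tests show: the pipeline's operating characteristics (filter
boundary behavior, test calibration, end-to-end sensitivity ≈ 90%+ with
essentially zero false nominations under the defaults) hold under the
generator's assumptions — a single clonal purity, independent read counts,
correctly specified segment profiles, and a signature matrix shared between
truth and refit. Real FFPE exomes violate several of these (subclonality,
segmentation error, purity misestimates, orientation-specific damage), so
the numbers bound what the design can achieve, not what any particular
cohort delivers.

## Numerical and degenerate-input choices

Zero-margin 2×2 tables raise a typed error that callers convert to "no
evidence". Variants with missing counts are routed to the removal log as
"unscorable" rather than dropped silently. Empty catalogs yield zero
exposures with a flag; sub-5-SNV catalogs yield Signature-3 no-calls. A
variant exactly on a segment boundary belongs to the segment whose 1-based
inclusive interval contains it; uncovered or multiply-covered loci raise
typed errors. EM refits run to a 1e-10 relative log-likelihood tolerance
(cap 400 iterations); LLR scores are clipped at 0. When several variants of
one gene in one patient survive, the most damaging consequence is reported
first — a reporting convention, not an inference.

## Known limitations

The Signature-3 caller is a self-contained likelihood-ratio procedure, not
a re-implementation of any published classifier's internals; its thresholds
are meaningful only together with its own calibration. Scar scores are
computed per chromosome rather than per arm, and the ≥ 42 threshold is
applied to raw sums. The generator models no subclonal structure beyond a
single purity, no indel realignment effects, and no methylation-based
silencing; structural-variant breakpoints and read-level data (FASTQ/BAM)
are out of scope.
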