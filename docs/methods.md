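# Methods

This note documents the models, rules and numerical choices behind
`intronapa`, and what the synthetic cohort does and does not establish.

## Isoform classification

All coordinates are 1-based closed intervals (the GTF convention) on both
strands; no internal conversion to half-open coordinates is performed, so a
single convention holds from parser to output. "3'-most" and "maximal" are
always taken in transcription direction: genomic maximum on `+`, genomic
minimum on `-` (implemented by comparing `pos` vs `-pos` keys). This makes
classification strictly mirror-symmetric: reflecting a gene's coordinates
and flipping its strand cannot change any label, and a property test
asserts this.

A coding transcript is an intronic-APA isoform iff its coding end differs
from the gene's maximal coding end (over coding transcripts) **and** its
transcript end differs from the gene's maximal transcript end (over all
transcripts). Ties are read strictly: a transcript whose coding end equals
the maximum is full-length even if its transcript body is shorter. The
transcript attaining the maximal coding end therefore always exists as a
full-length anchor, and a single-transcript gene can never have an APA
isoform.

Parser notes: only `exon`, `CDS` and `stop_codon` features are consumed; a
`stop_codon` adjacent to the CDS is merged into it so that GENCODE-style
(stop excluded) and RefSeq-style (stop included) annotations classify
identically. Transcripts are treated as coding iff they carry CDS
features; an explicit biotype filter is opt-in and never drops transcripts
lacking a biotype tag.

## Truncation ratio

`TR = Σ TPM(APA) / Σ TPM(APA + FL)` per gene and sample. The quantity is
TPM as provided; no pseudocount is added, and cells whose denominator is
zero are missing (NaN) rather than zero — a gene can pass the cohort-level
expression floor yet be unexpressed in individual samples, and those cells
carry no information about isoform preference. The expression floor
("gene TPM ≥ 1 in at least one sample") is applied to the gene-level sum
of labeled isoforms. TR is invariant to per-sample rescaling of the
expression column, so any within-sample normalization compatible with TPM
leaves it unchanged.

## Differential calling

*Pairwise mode* (few-replicate cell-line contrasts): APA and full-length
TPM are summed over replicates per condition and rounded to integer
pseudo-counts, and a 1-df Pearson chi-square (no continuity correction) is
applied to the 2×2 table. A zero row/column margin returns p = 1 with a
degenerate flag instead of an error. Significance: p < 0.05 and
|ΔTR| > 0.1.

*Cohort mode* (tumor vs normal): an unpaired two-sample t-test per gene on
per-sample TR values, Welch's variant by default because TCGA-style
tumor/normal group sizes are strongly unbalanced (a pooled-variance option
exists). Significance: p < 0.01. No multiple-testing correction is applied
by default — the thresholds are raw operating points of the workflow —
and Benjamini–Hochberg can be layered on externally if desired.

*Conservation rule*: per gene, the fraction of tumor samples strictly
above (or strictly below) the mean TR of normal samples; conserved at
fraction ≥ 0.8. Ties count for neither side; the reference can be switched
to the median. Cross-cancer frequency profiling then counts, per event,
the cancers in which it is conserved and classifies events as tumor-only,
normal-only or mixed.

## C-terminome peptides

Translation uses the standard nuclear codon table and stops at the first
stop codon. Two candidate routes:

* annotated last coding exon, in the frame implied by the cumulative CDS
  length upstream of that exon (the codon spanning the junction is
  skipped); reverse-complemented first on `-` strand; an internal stop in
  the annotated frame is an annotation inconsistency and excludes the
  transcript with a report;
* 3-frame translation of exon + intron-accumulation sequence. A frame is
  dropped when a stop codon *starts* within the exon-derived region
  (boundary-spanning stops count as in-exon) or when translation extends
  ≤ 6 nt (2 codons) beyond the exon boundary; the threshold is
  configurable.

Digestion cleaves after every K and R with no proline exception and no
missed cleavages, so peptides tile the parent exactly. Candidate filters:
no methionine, length ≥ 7, predicted charge `#K+#R+#H+1 > 1`. Because any
non-terminal tryptic peptide ends in K or R, the charge filter can only
ever remove a parent's C-terminal peptide — a property test asserts this.
The instrument-method charge assumption (+2, or +3 when histidine is
present) is emitted as metadata, not applied as a filter. Identical
peptide sequences from different transcripts collapse to one record with
multiple provenance entries.

## Domain loss

The differential region between a full-length protein and its truncated
isoform is everything beyond their longest common prefix — intronic APA
preserves the N-terminus, so prefix comparison is the appropriate string
rule. The truncated isoform's residues beyond the prefix (the
exonized-intron tail) are reported separately and never merged into loss
records. A Pfam domain is lost when its residue span overlaps the
differential region by ≥ 1 residue (fractional-overlap and
exclusive-exon-restricted modes available). Domain scanning itself is not
re-implemented; PfamScan tabular output is consumed, with out-of-range
hits dropped on validation. Summaries are domain × cancer count matrices
per side displayed as log2(count+1), their tumor/normal set intersection,
and domains recurrent in ≥ 5 cancers.

## Length landscape

The reference isoform per gene is the full-length transcript with the most
distal coding end, ties broken by maximal coding length, then transcript
id (fully deterministic). The 5' genomic boundary of an APA transcript's
3'-most exon — the point where it diverges into exonized intron — is
projected into reference coding coordinates (cumulative coding nt from the
start codon; a boundary inside a reference intron maps to the end of the
preceding coding exon); dividing by the reference coding length gives the
relative position, clipped to (0,1]. A 3'-boundary option exists and
counts the boundary nucleotide inclusively, so a reference's own last exon
maps to exactly 1. Positions upstream of the start codon flag the record
and exclude it from binning.

Bins are left-open/right-closed: (0,0.4], (0.4,0.8], (0.8,1.0] — exactly
0.4 is EARLY and exactly 0.8 is MID. Protein-length pairs are compared as
truncated/full ratios with a ±10% band by default (±20% selectable);
ratios above 1 (truncated isoform longer than the reference) are legal and
tracked.

## Prognostic modeling

Features (gene expression, TR, or their concatenation under `GE:`/`TR:`
namespaces after per-block variance filtering with floors 1 and 0.01,
sample variance ddof=1) are screened on the training 80% of samples: each
feature is dichotomized at its training median and kept at two-group
log-rank p < 0.05. The Cox model with elastic-net penalty is fit on
standardized training covariates (coefficients reported on the original
scale); the prognostic index `PI = Σ βᵢxᵢ` is computed on the held-out
20%, samples are split at the PI median into equal-size groups (odd n:
median sample to low risk; PI ties broken by sample id), and the split is
evaluated with Kaplan–Meier curves and the log-rank test. Screening
deliberately never touches test samples; a test asserts that permuting
test-set outcomes cannot change the selected features. The t-test top-k
selector (default k=100) serves the phenotype-classification harness and
likewise ranks on training samples only.

## Synthetic cohort

The generator emulates a TCGA-like tumor/normal contrast and is a
deterministic function of its seed.

* **Gene models**: 300 genes by default, each on its own contig; 70%
  receive one intronic-APA isoform. The reference has three coding exons
  (900 nt coding by default); the APA isoform shares exon 1 and replaces
  exon 2 by a composite last exon extending into intron 2, so its 3'-most
  exon's 5' boundary realizes a planted relative position exactly
  (`round(r·L)/L`). Genomic sequence is random, with the ORF laid in
  without in-frame stops, the junction-spanning codon chosen to avoid
  stops, and an explicit stop terminating the exonized extension — so the
  peptide route round-trips cleanly. About half the genes are placed on
  the `-` strand by mirroring.
* **Expression**: per gene and sample, total expression is log-normal
  (μ=3, σ=1 on the log scale, a typical TPM spread) and TR is Beta with
  concentration 50 and side-specific means: 0.3 baseline, +0.2 for effect
  genes (30% of APA genes, split between tumor- and normal-enriched).
  Transcript TPM is the exact TR-weighted split of the total, so
  quantification recovers the drawn TR to machine precision — the Beta
  draw, not measurement noise, is the biological variability.
* **Positions**: normal-enriched genes draw relative positions around
  0.25, tumor-enriched around 0.9 (sd 0.06), planting the EARLY/LATE
  dichotomy the bin analysis is meant to detect.
* **Survival**: exponential baseline (rate 0.1) scaled by `exp(Σβx)`,
  with independent uniform censoring whose horizon is solved so the
  expected censored fraction matches the configured 30% at the cohort
  mean hazard. The signal-split experiment uses two blocks of 4 signal
  (β=0.5) + 4 noise standard-normal covariates over 800 samples — the
  scale of the largest TCGA cohorts — so the held-out log-rank comparison
  between integrated and single-block models is adequately powered.

**What the synthetic cohort does not show.** Real RNA-seq has
quantification error correlated across isoforms, annotation errors,
multi-APA genes with partial isoform assignment, batch effects, and
non-proportional hazards; the generator has none of these. Passing tests
demonstrate that the implementation computes the intended quantities and
that the statistical machinery is calibrated (type-I ≈ 1% at the stated
operating point) and powered under the planted model — not that the
workflow's biological conclusions transfer to any particular real cohort.
Problem sizes in the test suite and acceptance script (300–500 genes,
120–800 samples, 50–2000 Monte-Carlo replicates) were chosen as the
smallest sizes at which the planted effects are decisively detectable.

## Numerical and degenerate-input choices

* Chi-square tables are rounded to integers (count-like input); zero
  margins return p=1 with a flag.
* The t-test path excludes genes with <2 non-missing values per group or
  zero variance in both groups (undefined statistic), logging them.
* `sksurv` requires `l1_ratio > 0`; ridge-dominant requests are clamped
  to 1e-3.
* Elastic-net fits standardize internally with population sd; constant
  columns are left unscaled rather than divided by zero.
* All orderings that affect output files (gene order, tie-breaks,
  manifest) are deterministic; the pipeline rerun under the same config is
  byte-identical.

## Known limitations

* The exonized-intron route requires intron-accumulation coordinates or
  sequences as input; discovering them from read coverage is out of scope.
* Domain hits are consumed from PfamScan output; no HMM scanning.
* The annotation-universe figures quoted for human GENCODE require the
  external GTF and are not part of the test suite; the classifier API
  accepts any GENCODE/RefSeq-dialect GTF for that purpose.
* The CLI's cohort tools assume sample-group tables with `tumor`/`normal`
  (or `case`/`control`) labels; more complex designs (paired samples,
  covariate adjustment) are not modeled.
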