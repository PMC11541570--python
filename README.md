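# intronapa

Profiling of **intronic alternative polyadenylation (intronic APA)** from
transcript-level expression data. Cleavage and polyadenylation inside an
intron produces a shorter mRNA isoform with an alternative last exon and,
usually, a C-terminally altered protein. This package implements a complete
annotation-driven workflow for studying that phenomenon in tumor/normal
cohorts and cell-line contrasts:

* **Isoform classification** — per gene, a coding transcript is an
  intronic-APA isoform iff (1) its coding end is not the gene's maximal
  coding end and (2) its transcript end is not the gene's maximal
  transcript end (both in transcription direction); everything else is
  full-length.
* **Truncation ratio (TR)** — the workflow's central statistic. Per gene
  *g* and sample *s*:

  `TR(g,s) = Σ TPM(APA isoforms) / Σ TPM(APA + full-length isoforms)`

* **Differential calling** — pairwise mode (2×2 chi-square on
  replicate-summed expression, *p* < 0.05 and |ΔTR| > 0.1) and cohort mode
  (Welch t-test on per-sample TR, *p* < 0.01), plus the 80% conservation
  rule: an event is cohort-conserved when ≥80% of tumor samples lie
  strictly beyond the normal-tissue mean TR in the called direction.
* **C-terminome peptide database** — in-silico candidate peptides for
  targeted mass spectrometry (SRM): last-coding-exon translation and
  3-frame exonized-intron translation, trypsin digestion (cut after K/R),
  removal of peptides with methionine or <7 residues, and the charge rule
  `charge = #K + #R + #H + 1 > 1`.
* **Domain loss** — differential protein sequences (residues beyond the
  longest common prefix of full-length and truncated isoforms) intersected
  with Pfam domain coordinates; tumor/normal domain-swap summaries on the
  `log2(count+1)` display scale.
* **Length landscape** — relative truncation positions in reference coding
  coordinates, binned EARLY (0–0.4], MID (0.4–0.8], LATE (0.8–1.0], and
  truncated/full protein-length ratios with a ±10% band.
* **Prognosis** — variance filter, training-set log-rank screen,
  elastic-net Cox model, prognostic index `PI = Σ βᵢxᵢ`, equal-size
  high/low risk groups, Kaplan–Meier/log-rank evaluation, and integration
  of gene-expression and TR covariate blocks.

A fully deterministic synthetic-cohort generator (`intronapa.synthetic`)
provides annotations, genome sequence, TPM matrices and survival data with
planted ground truth for every stage, so the whole pipeline is testable
end to end.

Intended users: computational biologists studying APA, isoform switches or
C-terminal proteome remodeling who have transcript-level TPM matrices
(e.g. from TCGA/Xena or kallisto/RSEM) and a GENCODE/RefSeq-style GTF.

## Worked example

The `analysis/` directory is a numbered narrative over a simulated
tumor/normal cohort (300 genes, 100 tumor + 20 normal samples, 210 genes
given an intronic-APA isoform, 63 with a planted TR shift of 0.2):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_classify_isoforms.py
python analysis/03_truncation_ratios.py
python analysis/04_differential_apa.py
```

which prints:

```
210 genes with >=1 intronic-APA isoform; 210 APA and 290 full-length transcripts over those genes
TR matrix: 300 genes x 120 samples (max |recovered - planted| = 2.22e-16)
64 significant events (p < 0.01); 63 also pass the 80% conservation rule
dichotomy: 32 tumor-enriched, 31 normal-enriched, 0 false calls on null genes
recall of planted effect genes: 1.00
```

The classifier recovers every planted truncated isoform; quantification
reproduces the generator's per-cell TR to machine precision; the cohort
test plus conservation rule recover all 63 planted effect genes — split
into the tumor-enriched/normal-enriched dichotomy — with zero false calls.
Steps `05`–`08` continue with the length landscape (planted EARLY/LATE
bimodality: 31 normal-side events EARLY, 32 tumor-side events LATE), the
SRM peptide database (825 unique candidate peptides), domain loss, and the
prognostic models (held-out log-rank p = 0.0023 for the TR model; the
integrated GE+TR model beats both single blocks in 19/20 replicates).

The same stages are available as a CLI (`intronapa simulate|classify|tr|
diff-pair|diff-cohort|conserve|freq|lengths|peptides|domains|survive|run`)
for use on real GTF/TPM inputs.

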