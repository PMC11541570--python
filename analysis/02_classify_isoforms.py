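#!/usr/bin/env python
"""Classify every transcript as intronic-APA or full-length.

Reads the GTF written by step 01 (through the same parser a real GENCODE
file would use), applies the two-condition rule, and reports the APA
universe: how many genes carry at least one truncated isoform.
"""

from pathlib import Path

from intronapa import annotation as ann

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    genes = ann.classify_all(ann.read_gtf(DATA / "annotation.gtf"))
    ann.write_label_table(genes, OUT / "labels.tsv")
    u = ann.count_apa_universe(genes)
    print(f"{u['n_genes_with_apa']} genes with >=1 intronic-APA isoform; "
          f"{u['n_apa_transcripts']} APA and "
          f"{u['n_full_length_transcripts']} full-length transcripts "
          "over those genes")
    print(f"label table -> {OUT / 'labels.tsv'}")


if __name__ == "__main__":
    main()
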