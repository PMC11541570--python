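#!/usr/bin/env python
"""Build the C-terminome SRM candidate peptide database.

Translates the last coding exon of every truncated isoform (annotated
route), applies the trypsin digest and the SRM candidate filters (no
methionine, length >= 7, charge state #K+#R+#H+1 > 1), and writes a
de-duplicated peptide FASTA + TSV with provenance and charge metadata.
"""

from pathlib import Path

from intronapa import annotation as ann
from intronapa.cterminome import GenomeSource, build_srm_database
from pyfaidx import Fasta

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    genes = ann.classify_all(ann.read_gtf(DATA / "annotation.gtf"))
    genome = GenomeSource(Fasta(str(DATA / "genome.fa")))
    db = build_srm_database(genes, genome)
    db.to_fasta(OUT / "peptides.fa")
    db.to_tsv(OUT / "peptides.tsv")

    charges = [entries[0].charge_state for entries in db.peptides.values()]
    n2 = sum(c == 2 for c in charges)
    print(f"{len(db)} unique candidate peptides from "
          f"{sum(len(g.apa_transcripts()) for g in genes)} truncated "
          f"isoforms ({len(db.exclusions)} exclusions)")
    print(f"charge states: {n2} at +2, {len(charges) - n2} higher")
    print(f"wrote {OUT / 'peptides.fa'} and {OUT / 'peptides.tsv'}")


if __name__ == "__main__":
    main()
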