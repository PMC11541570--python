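import numpy as np
import pytest

from intronapa import annotation as ann
from intronapa import synthetic as syn

TOY_GTF = """\
chr1\ttest\texon\t100\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1"; gene_name "GENEA"; transcript_type "protein_coding";
chr1\ttest\texon\t300\t500\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1"; gene_name "GENEA"; transcript_type "protein_coding";
chr1\ttest\tCDS\t120\t200\t.\t+\t0\tgene_id "gA"; transcript_id "gA.t1"; gene_name "GENEA"; transcript_type "protein_coding";
chr1\ttest\tCDS\t300\t420\t.\t+\t2\tgene_id "gA"; transcript_id "gA.t1"; gene_name "GENEA"; transcript_type "protein_coding";
chr1\ttest\texon\t100\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t2"; gene_name "GENEA"; transcript_type "protein_coding";
chr1\ttest\texon\t230\t260\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t2"; gene_name "GENEA"; transcript_type "protein_coding";
chr1\ttest\tCDS\t120\t200\t.\t+\t0\tgene_id "gA"; transcript_id "gA.t2"; gene_name "GENEA"; transcript_type "protein_coding";
chr1\ttest\tCDS\t230\t250\t.\t+\t2\tgene_id "gA"; transcript_id "gA.t2"; gene_name "GENEA"; transcript_type "protein_coding";
chr2\ttest\texon\t1000\t1200\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1"; gene_name "GENEB";
chr2\ttest\tCDS\t1050\t1200\t.\t-\t0\tgene_id "gB"; transcript_id "gB.t1"; gene_name "GENEB";
"""


@pytest.fixture
def toy_gtf(tmp_path):
    """Two genes: gA with a full-length and a truncated isoform, gB single."""
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-gene synthetic cohort shared across read-only tests."""
    cfg = syn.SyntheticConfig(seed=11, n_genes=60)
    annotation = syn.generate_annotation(cfg)
    expression = syn.generate_expression(cfg, annotation)
    return cfg, annotation, expression


def random_gene(rng: np.random.Generator, gene_idx: int) -> ann.GeneModel:
    """A structurally random gene for stress-testing classification.

    Transcripts get random exon chains; coding/transcript ends tie across
    transcripts with substantial probability, exercising the strict
    'is not the maximum' reading of the rule.
    """
    strand = "+" if rng.random() < 0.5 else "-"
    n_tx = int(rng.integers(1, 6))
    # a small pool of candidate ends makes ties frequent
    end_pool = sorted(rng.choice(np.arange(2000, 6000, 100), size=3))
    transcripts = []
    for j in range(n_tx):
        start = int(rng.integers(100, 800))
        tx_end = int(rng.choice(end_pool))
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(start + 50, tx_end - 50, 25),
                                 size=2 * (n_exons - 1), replace=False))
        bounds = [start] + [int(c) for c in cuts] + [tx_end]
        exons = [(bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons)]
        coding = rng.random() < 0.85
        cds = []
        if coding:
            # CDS spans a prefix of the exon chain, trimmed at both ends
            cds_end_exon = int(rng.integers(0, n_exons))
            for k, (s, e) in enumerate(exons[: cds_end_exon + 1]):
                cs = s + 10 if k == 0 else s
                ce = e - 10 if k == cds_end_exon else e
                if cs <= ce:
                    cds.append((cs, ce))
        t = ann.TranscriptModel(
            transcript_id=f"r{gene_idx}.t{j}", gene_id=f"r{gene_idx}",
            chrom=f"chrR{gene_idx}", strand=strand,
            exons=exons, cds=cds,
        )
        t.validate()
        transcripts.append(t)
    return ann.GeneModel(gene_id=f"r{gene_idx}", gene_name=f"R{gene_idx}",
                         transcripts=transcripts)


def brute_force_labels(gene: ann.GeneModel) -> dict[str, str]:
    """Independent pairwise-maximum classifier.

    A coding transcript is intronic-APA iff some other coding transcript
    has a strictly more-3' coding end AND some transcript (any) has a
    strictly more-3' transcript end, both in transcription direction.
    """
    labels = {}
    coding = [t for t in gene.transcripts if t.cds]
    for t in coding:
        beaten_coding = any(
            _more_3prime(o.coding_end, t.coding_end, t.strand)
            for o in coding if o is not t
        )
        beaten_end = any(
            _more_3prime(o.transcript_end, t.transcript_end, t.strand)
            for o in gene.transcripts if o is not t
        )
        labels[t.transcript_id] = (
            ann.APA if beaten_coding and beaten_end else ann.FULL_LENGTH
        )
    return labels


def _more_3prime(a: int, b: int, strand: str) -> bool:
    return a > b if strand == "+" else a < b
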